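"""Model-ready summary tables and the actogram figure.

Two tables feed the downstream mixed models (which are deliberately not
fitted here): an hourly brooding-rate table (binomial numerators of brooded
vs non-brooded minutes per local clock hour, the previous hour's brooding
proportion, a civil-dark night flag, ambient temperature, chick head length,
diel sine/cosine, and √minutes weights) and a brooding-efficiency table
(one row per brooding bout longer than 5 min with the median on-body
temperature after the first 5 min, when it has stabilized).

"Time of day" uses local standard time of the site, derived from longitude
(UTC+1 for the temperate site, UTC+4 for the desert site); no DST.
"""

from __future__ import annotations

from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import solar
from .accel import SensorTrace
from .bouts import BoutSet
from .config import PipelineConfig
from .io import ChickRecord
from .postprocess import _bin_labels


def diel_transform(hour: float) -> tuple[float, float]:
    """Map local clock time (hours, [0, 24)) onto the unit circle.

    θ = 2πh/24; returns (sin θ, cos θ) so midnight is (0, 1) and 06:00
    is (1, 0).
    """
    if not 0.0 <= hour < 24.0:
        raise ValueError(f"hour {hour} outside [0, 24)")
    theta = 2.0 * np.pi * hour / 24.0
    return float(np.sin(theta)), float(np.cos(theta))


def ztransform(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Mean-center and scale by the sample SD; returns (z, mean, sd)."""
    x = np.asarray(x, dtype=float)
    mean = float(np.nanmean(x))
    sd = float(np.nanstd(x, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-transform a constant column")
    return (x - mean) / sd, mean, sd


def _local_seconds(trace: SensorTrace, chick: ChickRecord) -> np.ndarray:
    """Bin start times as seconds on the local standard-time clock."""
    base = trace.start_utc + timedelta(hours=chick.utc_offset_hours)
    midnight = base.replace(hour=0, minute=0, second=0, microsecond=0)
    return (base - midnight).total_seconds() + trace.t5


def hourly_table(
    bouts: BoutSet,
    trace: SensorTrace,
    chick: ChickRecord,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Brooded / non-brooded minutes per local clock hour for one chick.

    Partial hours are kept (their √minutes weight is smaller); the night
    flag is evaluated at the hour's midpoint; minutes are exact interval
    coverage (fractional) unless ``cfg.round_minutes`` asks for integer
    binomial numerators.
    """
    cfg = cfg or PipelineConfig()
    if bouts.chick_id and bouts.chick_id != trace.chick_id:
        raise ValueError(
            f"bout set is for {bouts.chick_id!r} but trace for {trace.chick_id!r}"
        )
    t5 = trace.t5
    bw = trace.bin_s
    labels = _bin_labels(bouts, t5)
    local_s = _local_seconds(trace, chick)
    hour_idx = np.floor(local_s / 3600.0).astype(np.int64)

    df = pd.DataFrame(
        {
            "hour_idx": hour_idx,
            "brooded_s": np.where(labels == "brooding", bw, 0.0),
            "observed_s": bw,
            "tamb": trace.df["tamb5"].to_numpy(float),
        }
    )
    g = df.groupby("hour_idx").agg(
        brooded_s=("brooded_s", "sum"),
        observed_s=("observed_s", "sum"),
        tamb_mean=("tamb", "mean"),
    )

    rows = []
    prev: dict[int, float] = {}
    offset = timedelta(hours=chick.utc_offset_hours)
    for h_idx, r in g.iterrows():
        min_brooded = r["brooded_s"] / 60.0
        min_obs = r["observed_s"] / 60.0
        if cfg.round_minutes:
            min_brooded = float(round(min_brooded))
            min_obs = float(round(min_obs))
        clock_hour = int(h_idx % 24)
        # absolute UTC midpoint of the local clock hour
        day0 = (trace.start_utc + offset).replace(
            hour=0, minute=0, second=0, microsecond=0
        ) - offset
        mid_utc = day0 + timedelta(seconds=float(h_idx) * 3600.0 + 1800.0)
        elev_mid = solar.sun_elevation(mid_utc, chick.lat, chick.lon)
        sin_t, cos_t = diel_transform(float(clock_hour))
        prop = min_brooded / min_obs if min_obs > 0 else np.nan
        prev[h_idx] = prop
        rows.append(
            {
                "chick_id": chick.chick_id,
                "family_id": chick.family_id,
                "species": chick.species,
                "hour_start": clock_hour,
                "min_brooded": min_brooded,
                "min_not_brooded": min_obs - min_brooded,
                "prev_hour_prop": prev.get(h_idx - 1, np.nan),
                "night": bool(solar.night_flag(elev_mid)),
                "tamb_mean": r["tamb_mean"],
                "head_length": chick.head_length,
                "sin_t": sin_t,
                "cos_t": cos_t,
                "weight": np.sqrt(min_obs),
            }
        )
    return pd.DataFrame(rows)


def efficiency_table(
    bouts: BoutSet,
    trace: SensorTrace,
    chick: ChickRecord,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One row per brooding bout longer than 5 min: stabilized median temp.

    The first 5 min of each bout are excluded from the median, since the
    on-body temperature is still relaxing toward the parent's brood patch.
    """
    cfg = cfg or PipelineConfig()
    t5 = trace.t5
    rows = []
    for b in bouts.select("brooding"):
        if b.duration_s <= cfg.efficiency_min_bout_s:
            continue
        m = (t5 >= b.start_s + cfg.efficiency_skip_s) & (t5 < b.end_s - 1e-9)
        temps = trace.tbody5[m]
        temps = temps[np.isfinite(temps)]
        if temps.size == 0:
            continue
        mid_utc = trace.start_utc + timedelta(seconds=(b.start_s + b.end_s) / 2.0)
        elev = solar.sun_elevation(mid_utc, chick.lat, chick.lon)
        bm = (t5 >= b.start_s - 1e-9) & (t5 < b.end_s - 1e-9)
        rows.append(
            {
                "chick_id": chick.chick_id,
                "family_id": chick.family_id,
                "species": chick.species,
                "bout_start_s": b.start_s,
                "bout_dur_s": b.duration_s,
                "median_temp": float(np.median(temps)),
                "night": bool(solar.night_flag(elev)),
                "tamb_mean": float(np.nanmean(trace.df["tamb5"].to_numpy(float)[bm]))
                if bm.any()
                else np.nan,
                "head_length": chick.head_length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chick_id", "family_id", "species", "bout_start_s", "bout_dur_s",
            "median_temp", "night", "tamb_mean", "head_length",
        ],
    )


def overall_rate(
    bout_sets: list[BoutSet], traces: list[SensorTrace]
) -> dict:
    """Per-chick brooding proportion and the cohort median with quartiles."""
    if not bout_sets:
        raise ValueError("need at least one chick")
    per_chick = {}
    for bs, tr in zip(bout_sets, traces):
        observed = len(tr) * tr.bin_s
        per_chick[bs.chick_id] = (
            bs.total_duration("brooding") / observed if observed > 0 else np.nan
        )
    vals = np.array([v for v in per_chick.values() if np.isfinite(v)])
    q25, med, q75 = np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3
    return {
        "per_chick": per_chick,
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
    }


def render_actogram(trace: SensorTrace, bouts: BoutSet, path: Path) -> Path:
    """Five-channel actogram: ODBA, temperatures, light, sun, brooding."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t_h = trace.t5 / 3600.0
    fig, axes = plt.subplots(5, 1, figsize=(12, 9), sharex=True)
    axes[0].plot(t_h, trace.odba5, color="tab:orange", lw=0.5)
    axes[0].set_ylabel("ODBA (g)")
    axes[1].plot(t_h, trace.df["tamb5"], color="tab:blue", ls="--", lw=0.8,
                 label="ambient")
    axes[1].plot(t_h, trace.tbody5, color="tab:red", lw=0.8, label="on-body")
    axes[1].set_ylabel("T (°C)")
    axes[1].legend(loc="upper right", fontsize=7)
    axes[2].plot(t_h, np.maximum(trace.light5, 0.1), color="black", lw=0.5)
    axes[2].set_yscale("log")
    axes[2].axhline(50, color="grey", ls=":", lw=0.8)
    axes[2].set_ylabel("light (lx)")
    axes[3].plot(t_h, trace.sun_elev, color="goldenrod", lw=0.8)
    axes[3].axhline(-6, color="grey", ls=":", lw=0.8)
    axes[3].set_ylabel("sun (°)")
    for b in bouts.select("brooding"):
        axes[4].axvspan(b.start_s / 3600.0, b.end_s / 3600.0, color="tab:green")
    axes[4].set_ylim(0, 1)
    axes[4].set_yticks([])
    axes[4].set_ylabel("brooding")
    axes[4].set_xlabel("hours since deployment")
    fig.suptitle(f"chick {trace.chick_id}")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
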