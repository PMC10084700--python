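"""Acceleration preprocessing: autocalibration, filtering, ODBA, 5-s bins.

The chain mirrors standard biologging practice: (1) estimate per-axis offset
and gain from static (resting) windows by iteratively fitting the gravity
sphere; (2) split each axis into a gravitational part (centered moving
median, 0.2 Hz cut-off) and a dynamic part, smooth the dynamic part with a
2 Hz moving median, and sum absolute dynamic values over axes into ODBA;
(3) average ODBA, on-body temperature and light into 5-s bins, join ambient
temperature and sun elevation, and trim 30 min from each end of the
deployment (handling disturbance).

The "cut-off frequency" of a moving median is mapped to a window of
``round(fs/fc)`` samples (forced odd): a median over a window of duration
1/fc suppresses variation faster than fc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from . import solar
from .config import PipelineConfig
from .io import AmbientSeries, ChickRecord, RawTrace

TRACE5_COLS = ["t5", "odba5", "tbody5", "light5", "tamb5", "sun_elev", "n_valid"]


@dataclass
class CalibrationParams:
    """Per-axis accelerometer calibration: calibrated = (raw − offset) · gain."""

    offset: np.ndarray  # g, shape (3,)
    gain: np.ndarray  # dimensionless, shape (3,)
    n_static_windows: int
    converged: bool

    @classmethod
    def identity(cls, n_static_windows: int = 0) -> "CalibrationParams":
        return cls(np.zeros(3), np.ones(3), n_static_windows, converged=False)


@dataclass
class OdbaSeries:
    t: np.ndarray  # seconds, 25 Hz grid
    odba: np.ndarray  # g, ≥ 0


@dataclass
class SensorTrace:
    """5-s aggregated multichannel series for one chick."""

    chick_id: str
    df: pd.DataFrame  # columns TRACE5_COLS
    start_utc: datetime

    def __post_init__(self) -> None:
        missing = [c for c in TRACE5_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SensorTrace missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t5(self) -> np.ndarray:
        return self.df["t5"].to_numpy(float)

    @property
    def odba5(self) -> np.ndarray:
        return self.df["odba5"].to_numpy(float)

    @property
    def tbody5(self) -> np.ndarray:
        return self.df["tbody5"].to_numpy(float)

    @property
    def light5(self) -> np.ndarray:
        return self.df["light5"].to_numpy(float)

    @property
    def sun_elev(self) -> np.ndarray:
        return self.df["sun_elev"].to_numpy(float)

    @property
    def bin_s(self) -> float:
        t = self.t5
        return float(np.min(np.diff(t))) if len(t) > 1 else 5.0


# ---------------------------------------------------------------------------
# filtering


def median_filter(x: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Centered moving median with window ``round(fs/fc)`` samples (odd).

    Edges use truncated windows (no padding); a series shorter than the
    window degrades to the running median over the available samples.
    """
    if fc >= fs / 2:
        raise ValueError(f"cut-off {fc} Hz must be below Nyquist {fs / 2} Hz")
    w = int(round(fs / fc))
    if w % 2 == 0:
        w += 1
    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


# ---------------------------------------------------------------------------
# autocalibration


def find_static_windows(
    raw: RawTrace, win_s: float = 10.0, sd_thresh: float = 0.013
) -> list[int]:
    """Indices of non-overlapping windows that are static on all three axes.

    A window of ``win_s`` seconds is static when the per-axis sample SD is
    below ``sd_thresh`` (g) on ax, ay and az simultaneously.  Window ``i``
    covers samples ``[i*n, (i+1)*n)`` with ``n = round(win_s * fs)``.
    """
    fs = 1.0 / float(np.median(np.diff(raw.t_accel)))
    n = int(round(win_s * fs))
    n_win = len(raw.t_accel) // n
    if n_win == 0:
        return []
    out = []
    axes = np.stack([raw.ax, raw.ay, raw.az])[:, : n_win * n]
    sds = axes.reshape(3, n_win, n).std(axis=2)
    for i in range(n_win):
        if np.all(sds[:, i] < sd_thresh):
            out.append(i)
    return out


def static_window_means(raw: RawTrace, windows: list[int], win_s: float = 10.0
                        ) -> np.ndarray:
    """Mean acceleration 3-vector of each static window, shape (k, 3)."""
    fs = 1.0 / float(np.median(np.diff(raw.t_accel)))
    n = int(round(win_s * fs))
    axes = np.stack([raw.ax, raw.ay, raw.az])
    return np.array([axes[:, i * n : (i + 1) * n].mean(axis=1) for i in windows])


def _count_orientations(vectors: np.ndarray, min_angle_deg: float = 15.0) -> int:
    """Greedy count of distinct orientations separated by > min_angle_deg."""
    norms = np.linalg.norm(vectors, axis=1)
    units = vectors[norms > 0] / norms[norms > 0, None]
    reps: list[np.ndarray] = []
    cos_min = np.cos(np.radians(min_angle_deg))
    for u in units:
        if not any(float(u @ r) > cos_min for r in reps):
            reps.append(u)
    return len(reps)


def autocalibrate(
    static_means: np.ndarray,
    min_windows: int = 10,
    min_orientations: int = 3,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> CalibrationParams:
    """Estimate per-axis offset/gain so static vectors approach unit norm.

    Iterative closest-point sphere fit: each static mean is calibrated with
    the current parameters, projected onto the unit sphere (its closest
    point), and per-axis least squares re-estimates gain and offset;
    repeated until the parameters stabilize.  With too few windows or
    insufficient orientation diversity the identity calibration is
    returned with ``converged=False`` (never aborting the pipeline).
    """
    v = np.asarray(static_means, dtype=float)
    k = len(v)
    if k < min_windows or _count_orientations(v) < min_orientations:
        return CalibrationParams.identity(n_static_windows=k)

    offset = np.zeros(3)
    gain = np.ones(3)
    converged = False
    for _ in range(max_iter):
        cal = (v - offset) * gain
        norms = np.linalg.norm(cal, axis=1)
        if np.any(norms == 0):
            break
        target = cal / norms[:, None]
        new_gain = np.empty(3)
        new_off = np.empty(3)
        for ax in range(3):
            # target = a*v + b  ⇒  gain = a, offset = −b/a
            a, b = np.polyfit(v[:, ax], target[:, ax], 1)
            new_gain[ax] = a
            new_off[ax] = -b / a
        delta = float(np.max(np.abs(new_gain - gain)) + np.max(np.abs(new_off - offset)))
        gain, offset = new_gain, new_off
        if delta < tol:
            converged = True
            break

    ok = np.all((gain > 0.5) & (gain < 2.0)) and np.all(np.abs(offset) < 0.5)
    if not ok:
        return CalibrationParams.identity(n_static_windows=k)
    return CalibrationParams(offset, gain, n_static_windows=k, converged=converged)


def apply_calibration(raw: RawTrace, params: CalibrationParams) -> RawTrace:
    o, g = params.offset, params.gain
    return replace(
        raw,
        ax=(raw.ax - o[0]) * g[0],
        ay=(raw.ay - o[1]) * g[1],
        az=(raw.az - o[2]) * g[2],
    )


def calibrate_trace(raw: RawTrace, cfg: PipelineConfig | None = None
                    ) -> tuple[RawTrace, CalibrationParams]:
    """Find static windows, fit the calibration, and apply it."""
    cfg = cfg or PipelineConfig()
    wins = find_static_windows(raw, cfg.static_win_s, cfg.static_sd_g)
    means = static_window_means(raw, wins, cfg.static_win_s)
    params = autocalibrate(means) if len(means) else CalibrationParams.identity(0)
    return apply_calibration(raw, params), params


# ---------------------------------------------------------------------------
# ODBA


def compute_odba(
    raw_cal: RawTrace, hp_fc: float = 0.2, lp_fc: float = 2.0
) -> OdbaSeries:
    """Overall dynamic body acceleration on the 25 Hz grid.

    Per axis the gravitational component is the 0.2 Hz moving median and the
    dynamic component its residual; the residual is smoothed with the 2 Hz
    moving median, and ODBA sums absolute smoothed residuals over the axes.
    """
    fs = 1.0 / float(np.median(np.diff(raw_cal.t_accel)))
    odba = np.zeros_like(raw_cal.t_accel, dtype=float)
    for x in (raw_cal.ax, raw_cal.ay, raw_cal.az):
        dyn = x - median_filter(x, hp_fc, fs)
        odba += np.abs(median_filter(dyn, lp_fc, fs))
    return OdbaSeries(t=raw_cal.t_accel.copy(), odba=odba)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_trace(
    odba: OdbaSeries,
    raw: RawTrace,
    ambient: AmbientSeries,
    chick: ChickRecord,
    cfg: PipelineConfig | None = None,
) -> SensorTrace:
    """Average all channels into 5-s bins and join ambient + sun elevation.

    Bin edges sit on multiples of the bin width; bins without any 25 Hz
    sample are dropped.  Ambient temperature is joined by nearest-time
    interpolation; a gap longer than 1 h overlapping the trace leaves the
    affected bins missing with a warning.
    """
    cfg = cfg or PipelineConfig()
    bw = cfg.bin_s

    fast = pd.DataFrame({"bin": np.floor(odba.t / bw).astype(np.int64),
                         "odba": odba.odba})
    g = fast.groupby("bin")["odba"]
    agg = pd.DataFrame({"odba5": g.mean(), "n_valid": g.size()})

    slow = pd.DataFrame(
        {
            "bin": np.floor(raw.t_slow / bw).astype(np.int64),
            "tbody": raw.tbody,
            "light": raw.light,
        }
    )
    slow_agg = slow.groupby("bin")[["tbody", "light"]].mean()
    agg = agg.join(slow_agg.rename(columns={"tbody": "tbody5", "light": "light5"}))

    agg = agg.reset_index()
    agg["t5"] = agg["bin"] * bw

    centers = agg["t5"].to_numpy(float) + bw / 2.0
    t_amb = ambient.seconds_since(raw.start_utc)
    tamb5 = np.interp(centers, t_amb, ambient.tamb)
    # blank out bins sitting inside an ambient gap longer than 1 h
    gaps = np.flatnonzero(np.diff(t_amb) > 3600.0)
    if len(gaps):
        for gi in gaps:
            inside = (centers > t_amb[gi]) & (centers < t_amb[gi + 1])
            if inside.any():
                warnings.warn(
                    f"ambient gap of {t_amb[gi + 1] - t_amb[gi]:.0f} s overlaps "
                    f"trace {raw.chick_id}; tamb5 left missing", stacklevel=2
                )
                tamb5[inside] = np.nan
    out_of_range = (centers < t_amb[0]) | (centers > t_amb[-1])
    tamb5[out_of_range] = np.nan
    agg["tamb5"] = tamb5

    times = np.datetime64(
        raw.start_utc.replace(tzinfo=None), "ns"
    ) + (centers * 1e9).astype("timedelta64[ns]")
    agg["sun_elev"] = solar.sun_elevation(times, chick.lat, chick.lon)

    return SensorTrace(
        chick_id=raw.chick_id,
        df=agg[TRACE5_COLS].sort_values("t5"),
        start_utc=raw.start_utc,
    )


def trim_edges(trace: SensorTrace, trim_s: float = 1800.0) -> SensorTrace:
    """Drop the first and last ``trim_s`` seconds of the aggregated trace."""
    if len(trace) == 0:
        return trace
    t = trace.t5
    bw = trace.bin_s
    lo, hi = t[0] + trim_s, t[-1] + bw - trim_s
    keep = (t >= lo) & (t + bw <= hi)
    if not keep.any():
        warnings.warn(
            f"trace {trace.chick_id} shorter than twice the trim ({trim_s} s); "
            "nothing left", stacklevel=2
        )
    return SensorTrace(trace.chick_id, trace.df.loc[keep], trace.start_utc)


def preprocess_chick(
    raw: RawTrace,
    ambient: AmbientSeries,
    chick: ChickRecord,
    cfg: PipelineConfig | None = None,
) -> tuple[SensorTrace, CalibrationParams]:
    """Full preprocessing for one chick: calibrate → ODBA → bin → trim."""
    cfg = cfg or PipelineConfig()
    if cfg.autocalibrate:
        raw_cal, params = calibrate_trace(raw, cfg)
    else:
        raw_cal, params = raw, CalibrationParams.identity()
    odba = compute_odba(raw_cal, cfg.highpass_fc_hz, cfg.lowpass_fc_hz)
    trace = aggregate_trace(odba, raw_cal, ambient, chick, cfg)
    return trim_edges(trace, cfg.trim_s), params
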