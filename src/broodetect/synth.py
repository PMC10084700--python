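"""Synthetic multichannel datalogger recordings with ground-truth states.

The generator emulates the statistical structure the detection pipeline
relies on, per chick:

* **ambient temperature** — a diel sinusoid peaking mid-afternoon plus
  AR(1) noise;
* **behavior** — alternating semi-Markov states: each activity (foraging)
  bout is followed by an inactive bout that is *brooding* with probability
  logistic(intercept + slope·z(tamb) + night_effect·night), otherwise a
  daytime *shade-rest* (under vegetation) or an *other-rest*; durations are
  log-normal per state;
* **on-body temperature** — first-order relaxation dT/dt = (T_target − T)/τ
  toward a species-specific brooding equilibrium T_eq while brooded and
  toward ambient + 1 °C otherwise, plus sensor noise;
* **light** — a daylight level (log-uniform 10⁴–10⁵ lx scaled by sun
  elevation), near-zero at night, 200–2,000 lx in plant shade and
  0–20 lx while brooded (the chick's back is under the parent), so the
  50 lx rule is informative by construction;
* **acceleration** — a slowly rotating gravity vector plus band-limited
  dynamic noise whose amplitude depends on the state, then distorted by a
  configurable sensor miscalibration (inverted later by autocalibration).

Ground truth (per-second state sequence, true bout intervals, true brooding
proportion) is returned alongside, so every pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.ndimage import uniform_filter1d

from . import io as bio
from . import solar
from .bouts import Bout, BoutSet
from .io import AmbientSeries, ChickRecord, RawTrace

STATES = ("brooding", "foraging", "shade_rest", "other_rest")


@dataclass
class SimConfig:
    """Simulator parameters; presets :func:`nl_preset` / :func:`rwl_preset`."""

    species: str = "NL"
    duration_h: float = 48.0
    fs_accel: float = 25.0
    start_utc: datetime = field(
        default_factory=lambda: datetime(2019, 5, 10, 0, 0, tzinfo=timezone.utc)
    )
    lat: float = solar.SITE_NL[0]
    lon: float = solar.SITE_NL[1]
    # ambient model
    ambient_mean_c: float = 15.0
    ambient_amp_c: float = 8.0
    ambient_noise_sd: float = 0.8
    ambient_ar1: float = 0.999
    # brooding decision logistic; tamb is z-scored against a fixed reference
    # (not the chick's own ambient model, so cohorts at different sites
    # genuinely differ in brooding probability)
    brood_intercept: float = 0.0
    brood_temp_slope: float = -1.5  # per z(tamb), ≤ 0
    brood_night_effect: float = 3.0  # ≥ 0
    z_ref_mean_c: float = 20.0
    z_ref_sd_c: float = 8.0
    # bout durations: log-normal (mu, sigma) of seconds
    dur_brooding: tuple[float, float] = (np.log(900.0), 0.5)
    dur_foraging: tuple[float, float] = (np.log(600.0), 0.6)
    dur_shade: tuple[float, float] = (np.log(400.0), 0.5)
    dur_other_rest: tuple[float, float] = (np.log(240.0), 0.5)
    # thermal model
    tau_s: float = 120.0
    t_eq_c: float = 37.2
    tbody_noise_sd: float = 0.02
    # light model (lx)
    day_light_range: tuple[float, float] = (1e4, 1e5)
    shade_light_range: tuple[float, float] = (200.0, 2000.0)
    brood_light_range: tuple[float, float] = (0.0, 20.0)
    night_light_lx: float = 1.0
    shade_prob: float = 0.6  # daytime non-brooding rest is shade w.p. this
    # acceleration model (g)
    odba_sd_active: float = 0.25
    odba_sd_brooding: float = 0.004
    odba_sd_rest: float = 0.006
    gravity_walk_deg_s: float = 0.3
    miscal_offset: tuple[float, float, float] = (0.03, -0.02, 0.01)
    miscal_gain: tuple[float, float, float] = (1.02, 0.98, 1.01)
    seed: int = 0
    #: separate seed for the ambient weather noise; a cohort shares one value
    #: so all chicks at a site experience the same weather
    ambient_seed: int | None = None

    def validate(self) -> None:
        if self.species not in ("NL", "RWL"):
            raise ValueError(f"unknown species preset {self.species!r}")
        if self.tau_s <= 0:
            raise ValueError("thermal time constant must be positive")
        if self.brood_temp_slope > 0:
            raise ValueError("temperature slope must be ≤ 0")
        if self.brood_night_effect < 0:
            raise ValueError("night effect must be ≥ 0")
        for name in ("ambient_noise_sd", "tbody_noise_sd", "odba_sd_active",
                     "odba_sd_brooding", "odba_sd_rest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")


def nl_preset(**overrides) -> SimConfig:
    """Temperate-site preset: cool diel ambient, warm brood patch (37.2 °C)."""
    return replace(SimConfig(), **overrides)


def rwl_preset(**overrides) -> SimConfig:
    """Desert-site preset: hot diel ambient, cooler equilibrium (35.0 °C)."""
    cfg = SimConfig(
        species="RWL",
        lat=solar.SITE_RWL[0],
        lon=solar.SITE_RWL[1],
        start_utc=datetime(2019, 4, 10, 0, 0, tzinfo=timezone.utc),
        ambient_mean_c=32.0,
        ambient_amp_c=8.0,
        t_eq_c=35.0,
        brood_temp_slope=-1.0,
    )
    return replace(cfg, **overrides)


@dataclass
class SimTruth:
    """Ground truth for one simulated chick."""

    chick_id: str
    state_per_s: np.ndarray  # one STATES entry per second
    bouts: BoutSet  # true bouts over all states (brooding label kept)
    brooding_prop: float
    config: SimConfig


# ---------------------------------------------------------------------------


def _simulate_states(
    cfg: SimConfig, tamb: np.ndarray, is_night: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Alternating semi-Markov state sequence at 1 Hz."""
    n = len(tamb)
    z_sd = max(cfg.z_ref_sd_c, 1e-6)
    state = np.empty(n, dtype=object)
    t = 0
    active = True  # start in a foraging bout
    dur_map = {
        "brooding": cfg.dur_brooding,
        "foraging": cfg.dur_foraging,
        "shade_rest": cfg.dur_shade,
        "other_rest": cfg.dur_other_rest,
    }
    while t < n:
        if active:
            name = "foraging"
        else:
            z = (tamb[t] - cfg.z_ref_mean_c) / z_sd
            eta = (
                cfg.brood_intercept
                + cfg.brood_temp_slope * z
                + cfg.brood_night_effect * float(is_night[t])
            )
            p_brood = 1.0 / (1.0 + np.exp(-eta))
            if rng.random() < p_brood:
                name = "brooding"
            elif not is_night[t] and rng.random() < cfg.shade_prob:
                name = "shade_rest"
            else:
                name = "other_rest"
        mu, sigma = dur_map[name]
        dur = max(int(round(rng.lognormal(mu, sigma))), 30)
        state[t : t + dur] = name
        t += dur
        active = not active
    return state


def _true_bouts(chick_id: str, state: np.ndarray) -> BoutSet:
    changes = np.flatnonzero(state[1:] != state[:-1]) + 1
    starts = np.concatenate([[0], changes])
    ends = np.concatenate([changes, [len(state)]])
    bouts = []
    for s, e in zip(starts, ends):
        label = "brooding" if state[s] == "brooding" else (
            "active" if state[s] == "foraging" else "other_inactive"
        )
        bouts.append(Bout(float(s), float(e), label, "truth"))
    return BoutSet(chick_id, bouts)


def _simulate_tbody(cfg: SimConfig, tamb: np.ndarray, brooding: np.ndarray
                    ) -> np.ndarray:
    target = np.where(brooding, cfg.t_eq_c, tamb + 1.0)
    n = len(tamb)
    t_body = np.empty(n)
    t_body[0] = target[0] if brooding[0] else tamb[0] + 1.0
    # exact discretization of the linear relaxation over 1-s steps
    decay = np.exp(-1.0 / cfg.tau_s)
    for i in range(1, n):
        t_body[i] = target[i] + (t_body[i - 1] - target[i]) * decay
    return t_body


def _simulate_light(
    cfg: SimConfig,
    state: np.ndarray,
    elev: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(state)
    lo, hi = cfg.day_light_range
    day_base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    light = day_base * np.clip(np.sin(np.radians(np.maximum(elev, 0.0))), 0.0, 1.0)
    night = elev <= 0.0
    light[night] = rng.uniform(0.0, cfg.night_light_lx, size=int(night.sum()))
    shade = state == "shade_rest"
    light[shade] = rng.uniform(*cfg.shade_light_range, size=int(shade.sum()))
    brood = state == "brooding"
    light[brood] = rng.uniform(*cfg.brood_light_range, size=int(brood.sum()))
    return np.maximum(light, 0.0)


def _simulate_accel(
    cfg: SimConfig, state: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """True (calibrated) acceleration, shape (n_fast, 3)."""
    fs = cfg.fs_accel
    n_fast = int(len(state) * fs)
    # slowly rotating gravity: smoothed random walks on two angles
    step = np.radians(cfg.gravity_walk_deg_s) / np.sqrt(fs)
    theta = np.cumsum(rng.normal(0.0, step, size=n_fast))
    phi = np.cumsum(rng.normal(0.0, step, size=n_fast))
    theta = uniform_filter1d(theta, size=int(5 * fs))
    phi = uniform_filter1d(phi, size=int(5 * fs))
    gravity = np.stack(
        [
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ],
        axis=1,
    )
    sd_map = {
        "foraging": cfg.odba_sd_active,
        "brooding": cfg.odba_sd_brooding,
        "shade_rest": cfg.odba_sd_rest,
        "other_rest": cfg.odba_sd_rest,
    }
    sd_slow = np.array([sd_map[s] for s in state])
    sd_fast = np.repeat(sd_slow, int(fs))[:n_fast, None]
    dyn = rng.normal(0.0, 1.0, size=(n_fast, 3))
    dyn = uniform_filter1d(dyn, size=3, axis=0)  # band-limit the noise
    return gravity + dyn * sd_fast


def simulate_chick(cfg: SimConfig, chick_id: str = "sim01"
                   ) -> tuple[RawTrace, AmbientSeries, SimTruth]:
    """Generate one chick's raw recording, ambient series and ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_h * 3600.0))
    t_slow = np.arange(n, dtype=float)

    start = cfg.start_utc
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    times = np.datetime64(start.replace(tzinfo=None), "ns") + (
        t_slow * 1e9
    ).astype("timedelta64[ns]")
    elev = np.asarray(solar.sun_elevation(times, cfg.lat, cfg.lon))
    is_night = solar.night_flag(elev)

    # ambient: diel sinusoid peaking at 15:00 local + AR(1) noise
    local_h = ((t_slow / 3600.0) + start.hour + start.minute / 60.0
               + cfg.lon / 15.0) % 24.0
    diel = cfg.ambient_mean_c + cfg.ambient_amp_c * np.cos(
        2.0 * np.pi * (local_h - 15.0) / 24.0
    )
    innov_sd = cfg.ambient_noise_sd * np.sqrt(1.0 - cfg.ambient_ar1**2)
    amb_seed = cfg.ambient_seed if cfg.ambient_seed is not None else cfg.seed
    rng_amb = np.random.default_rng(amb_seed + 10007)
    noise = lfilter([1.0], [1.0, -cfg.ambient_ar1],
                    rng_amb.normal(0.0, innov_sd, size=n))
    tamb = diel + noise

    state = _simulate_states(cfg, tamb, is_night, rng)
    brooding = state == "brooding"
    tbody = _simulate_tbody(cfg, tamb, brooding)
    tbody_meas = tbody + rng.normal(0.0, cfg.tbody_noise_sd, size=n)
    light = _simulate_light(cfg, state, elev, rng)

    accel_true = _simulate_accel(cfg, state, rng)
    gain = np.asarray(cfg.miscal_gain)
    offset = np.asarray(cfg.miscal_offset)
    accel_raw = accel_true / gain + offset  # inverted by (raw − o) · g
    t_accel = np.arange(accel_true.shape[0], dtype=float) / cfg.fs_accel

    raw = RawTrace(
        chick_id=chick_id,
        t_accel=t_accel,
        ax=accel_raw[:, 0],
        ay=accel_raw[:, 1],
        az=accel_raw[:, 2],
        t_slow=t_slow,
        tbody=tbody_meas,
        light=light,
        start_utc=start,
    )
    # ambient sampled every 5 min, as a field logger would
    amb_idx = np.arange(0, n, 300)
    ambient = AmbientSeries(t_utc=times[amb_idx], tamb=tamb[amb_idx])
    truth = SimTruth(
        chick_id=chick_id,
        state_per_s=state,
        bouts=_true_bouts(chick_id, state),
        brooding_prop=float(np.mean(brooding)),
        config=cfg,
    )
    return raw, ambient, truth


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(
    cfg_base: SimConfig,
    n_chicks: int,
    seed: int,
    out_dir: Path | None = None,
    force: bool = False,
) -> tuple[list[RawTrace], AmbientSeries, list[ChickRecord], list[SimTruth]]:
    """Simulate ``n_chicks`` chicks with per-chick seeds derived from ``seed``.

    When ``out_dir`` is given, writes the on-disk layout the io module reads
    (`<id>_accel.csv`, `<id>_slow.csv`, `chicks.csv`, `ambient.csv`) plus
    `truth.csv` (true bouts) and `truth_summary.csv` (true proportions).
    """
    if n_chicks < 1:
        raise ValueError("need at least one chick")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_chicks)
    cohort_ambient_seed = int(master.integers(0, 2**31 - 1))
    meta_rng = np.random.default_rng(child_seeds[0] ^ 0x5EED)

    raws, truths, chicks = [], [], []
    ambient = None
    for i in range(n_chicks):
        cid = f"{cfg_base.species.lower()}{i + 1:02d}"
        cfg = replace(
            cfg_base, seed=int(child_seeds[i]), ambient_seed=cohort_ambient_seed
        )
        raw, amb, truth = simulate_chick(cfg, chick_id=cid)
        if ambient is None:
            ambient = amb  # one site-level ambient series per cohort
        head = float(meta_rng.uniform(25.0, 40.0))
        mass0 = float(meta_rng.uniform(15.0, 55.0))
        chick = ChickRecord(
            chick_id=cid,
            family_id=f"f{i + 1:02d}",
            species=cfg_base.species,
            head_length=head,
            mass_start=mass0,
            mass_end=mass0 + float(meta_rng.uniform(0.0, 8.0)),
            deploy_start=raw.start_utc,
            deploy_end=raw.start_utc + timedelta(hours=cfg.duration_h),
            lat=cfg.lat,
            lon=cfg.lon,
        )
        raws.append(raw)
        truths.append(truth)
        chicks.append(chick)

    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not force:
            raise FileExistsError(f"{out_dir} is not empty (use force)")
        out_dir.mkdir(parents=True, exist_ok=True)
        for raw in raws:
            bio.write_raw_trace(raw, out_dir)
        bio.write_chicks(chicks, out_dir / "chicks.csv")
        bio.write_ambient(ambient, out_dir / "ambient.csv")
        truth_rows = []
        for truth in truths:
            st = truth.state_per_s
            changes = np.flatnonzero(st[1:] != st[:-1]) + 1
            starts = np.concatenate([[0], changes])
            ends = np.concatenate([changes, [len(st)]])
            for s, e in zip(starts, ends):
                truth_rows.append(
                    {
                        "chick_id": truth.chick_id,
                        "start_s": float(s),
                        "end_s": float(e),
                        "state": str(st[s]),
                    }
                )
        pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
        pd.DataFrame(
            [
                {"chick_id": t.chick_id, "true_brooding_prop": t.brooding_prop}
                for t in truths
            ]
        ).to_csv(out_dir / "truth_summary.csv", index=False)
    return raws, ambient, chicks, truths
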