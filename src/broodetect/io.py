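"""Readers and writers for all on-disk artifacts.

All files are plain CSV.  Dual-rate raw recordings are split into two files
per chick (`<chick_id>_accel.csv` at 25 Hz and `<chick_id>_slow.csv` at
1 Hz) so no row-interleaving dialect is needed; each carries the absolute
UTC start of the deployment in a single sidecar comment line

    # start_utc=2019-05-01T06:00:00+00:00

and all in-file times are seconds since that start.  Missing slow-channel
samples are empty fields and stay missing (NaN) in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .bouts import Bout, BoutSet

if TYPE_CHECKING:  # pragma: no cover
    from .accel import SensorTrace

NOMINAL_FS_ACCEL = 25.0  # Hz
NOMINAL_FS_SLOW = 1.0  # Hz

SPECIES = ("NL", "RWL")
MIN_DEPLOY_MASS_G = 14.0


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the declared format."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RawTrace:
    """One chick's raw dual-rate recording.

    25 Hz tri-axial acceleration (g) plus 1 Hz on-body temperature (°C) and
    light level (lx), with all times in seconds since ``start_utc``.
    """

    chick_id: str
    t_accel: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    t_slow: np.ndarray
    tbody: np.ndarray
    light: np.ndarray
    start_utc: datetime

    def validate(self) -> None:
        for name, t, fs in (
            ("accel", self.t_accel, NOMINAL_FS_ACCEL),
            ("slow", self.t_slow, NOMINAL_FS_SLOW),
        ):
            if len(t) == 0:
                raise FormatError(f"{name} channel is empty")
            dt = np.diff(t)
            if len(dt) and np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise FormatError(
                    f"{name} time not strictly increasing at row {bad + 1}"
                )
            if len(dt):
                mean_dt = float(np.mean(dt))
                if abs(mean_dt * fs - 1.0) > 0.01:
                    raise FormatError(
                        f"{name} sampling rate {1.0 / mean_dt:.3f} Hz deviates "
                        f"more than 1% from nominal {fs:g} Hz"
                    )
        finite_light = self.light[np.isfinite(self.light)]
        if finite_light.size and finite_light.min() < 0:
            raise FormatError("negative light level")
        # both channels must span the same interval within one slow sample
        tol = 1.0 / NOMINAL_FS_SLOW
        if (
            abs(self.t_accel[0] - self.t_slow[0]) > tol
            or abs(self.t_accel[-1] - self.t_slow[-1]) > tol
        ):
            raise FormatError(
                "accel and slow channels do not cover the same interval "
                f"(accel [{self.t_accel[0]:.2f}, {self.t_accel[-1]:.2f}] s, "
                f"slow [{self.t_slow[0]:.2f}, {self.t_slow[-1]:.2f}] s)"
            )


@dataclass(frozen=True)
class ChickRecord:
    """Identity, morphometrics and deployment window of one chick."""

    chick_id: str
    family_id: str
    species: str
    head_length: float  # mm, proxy for age
    mass_start: float  # g at deployment
    mass_end: float  # g at retrieval
    deploy_start: datetime
    deploy_end: datetime
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise FormatError(f"unknown species {self.species!r}")
        if self.deploy_end <= self.deploy_start:
            raise FormatError("deploy_end must be after deploy_start")
        if self.head_length <= 0:
            raise FormatError("head_length must be positive")
        if self.mass_start < MIN_DEPLOY_MASS_G:
            raise FormatError(
                f"mass_start {self.mass_start} g below deployment minimum "
                f"{MIN_DEPLOY_MASS_G} g"
            )

    @property
    def utc_offset_hours(self) -> int:
        """Local standard-time offset of the site, from longitude."""
        return int(round(self.lon / 15.0))


@dataclass
class AmbientSeries:
    """Near-ground ambient temperature in direct sun, absolute timestamps."""

    t_utc: np.ndarray  # datetime64[ns], increasing; gaps permitted
    tamb: np.ndarray  # °C

    def validate(self) -> None:
        if len(self.t_utc) < 1:
            raise FormatError("empty ambient series")
        if np.any(np.diff(self.t_utc.astype("datetime64[ns]").astype(np.int64)) <= 0):
            raise FormatError("ambient timestamps not strictly increasing")

    def seconds_since(self, start_utc: datetime) -> np.ndarray:
        start = np.datetime64(start_utc.replace(tzinfo=None), "ns")
        return (self.t_utc.astype("datetime64[ns]") - start) / np.timedelta64(1, "s")


# ---------------------------------------------------------------------------
# sidecar helpers


def _write_start_line(fh, start_utc: datetime) -> None:
    if start_utc.tzinfo is None:
        start_utc = start_utc.replace(tzinfo=timezone.utc)
    fh.write(f"# start_utc={start_utc.isoformat()}\n")


def _read_start_line(path: Path) -> datetime:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# start_utc="):
        raise FormatError(f"{path}: missing '# start_utc=' sidecar line")
    ts = datetime.fromisoformat(first.removeprefix("# start_utc="))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _read_csv(path: Path, columns: list[str], skiprows: int = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, skiprows=skiprows)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} (header line "
                          f"{skiprows + 1})")
    return df


# ---------------------------------------------------------------------------
# raw traces


def write_raw_trace(raw: RawTrace, out_dir: Path) -> tuple[Path, Path]:
    """Write `<chick_id>_accel.csv` and `<chick_id>_slow.csv`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    accel_path = out_dir / f"{raw.chick_id}_accel.csv"
    slow_path = out_dir / f"{raw.chick_id}_slow.csv"
    with open(accel_path, "w") as fh:
        _write_start_line(fh, raw.start_utc)
        pd.DataFrame(
            {"t": raw.t_accel, "ax": raw.ax, "ay": raw.ay, "az": raw.az}
        ).to_csv(fh, index=False, float_format="%.6f")
    with open(slow_path, "w") as fh:
        _write_start_line(fh, raw.start_utc)
        pd.DataFrame(
            {"t": raw.t_slow, "tbody": raw.tbody, "light": raw.light}
        ).to_csv(fh, index=False, float_format="%.4f")
    return accel_path, slow_path


def read_raw_trace(accel_path: Path, slow_path: Path | None = None) -> RawTrace:
    """Read one chick's raw recording from its accel/slow CSV pair.

    ``slow_path`` defaults to the accel path with ``_accel`` replaced by
    ``_slow``.  Channel invariants (monotone time, sampling rate within 1%,
    non-negative light, matching coverage) are validated on read.
    """
    accel_path = Path(accel_path)
    if slow_path is None:
        slow_path = accel_path.with_name(
            accel_path.name.replace("_accel", "_slow")
        )
    slow_path = Path(slow_path)
    chick_id = accel_path.name.removesuffix("_accel.csv")
    start = _read_start_line(accel_path)
    start_slow = _read_start_line(slow_path)
    if abs((start - start_slow).total_seconds()) > 1.0:
        raise FormatError("accel and slow files disagree on start_utc")
    acc = _read_csv(accel_path, ["t", "ax", "ay", "az"], skiprows=1)
    slow = _read_csv(slow_path, ["t", "tbody", "light"], skiprows=1)
    raw = RawTrace(
        chick_id=chick_id,
        t_accel=acc["t"].to_numpy(float),
        ax=acc["ax"].to_numpy(float),
        ay=acc["ay"].to_numpy(float),
        az=acc["az"].to_numpy(float),
        t_slow=slow["t"].to_numpy(float),
        tbody=slow["tbody"].to_numpy(float),
        light=slow["light"].to_numpy(float),
        start_utc=start,
    )
    raw.validate()
    return raw


# ---------------------------------------------------------------------------
# chick metadata

_CHICK_COLS = [
    "chick_id", "family_id", "species", "head_length", "mass_start",
    "mass_end", "deploy_start", "deploy_end", "lat", "lon",
]


def write_chicks(chicks: list[ChickRecord], path: Path) -> None:
    rows = []
    for c in chicks:
        rows.append(
            {
                "chick_id": c.chick_id,
                "family_id": c.family_id,
                "species": c.species,
                "head_length": c.head_length,
                "mass_start": c.mass_start,
                "mass_end": c.mass_end,
                "deploy_start": c.deploy_start.isoformat(),
                "deploy_end": c.deploy_end.isoformat(),
                "lat": c.lat,
                "lon": c.lon,
            }
        )
    pd.DataFrame(rows, columns=_CHICK_COLS).to_csv(path, index=False)


def read_chicks(path: Path) -> list[ChickRecord]:
    df = _read_csv(Path(path), _CHICK_COLS)
    out = []
    for _, r in df.iterrows():
        out.append(
            ChickRecord(
                chick_id=str(r["chick_id"]),
                family_id=str(r["family_id"]),
                species=str(r["species"]),
                head_length=float(r["head_length"]),
                mass_start=float(r["mass_start"]),
                mass_end=float(r["mass_end"]),
                deploy_start=datetime.fromisoformat(str(r["deploy_start"])),
                deploy_end=datetime.fromisoformat(str(r["deploy_end"])),
                lat=float(r["lat"]),
                lon=float(r["lon"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ambient series


def write_ambient(amb: AmbientSeries, path: Path) -> None:
    pd.DataFrame(
        {"t": pd.to_datetime(amb.t_utc).strftime("%Y-%m-%dT%H:%M:%S"),
         "tamb": amb.tamb}
    ).to_csv(path, index=False, float_format="%.3f")


def read_ambient(path: Path) -> AmbientSeries:
    df = _read_csv(Path(path), ["t", "tamb"])
    amb = AmbientSeries(
        t_utc=pd.to_datetime(df["t"]).to_numpy(),
        tamb=df["tamb"].to_numpy(float),
    )
    amb.validate()
    return amb


# ---------------------------------------------------------------------------
# aggregated traces

_TRACE5_COLS = ["t5", "odba5", "tbody5", "light5", "tamb5", "sun_elev", "n_valid"]


def write_trace5(trace: "SensorTrace", path: Path) -> None:
    with open(path, "w") as fh:
        _write_start_line(fh, trace.start_utc)
        trace.df.to_csv(fh, index=False, float_format="%.6f")


def read_trace5(path: Path, chick_id: str | None = None) -> "SensorTrace":
    from .accel import SensorTrace

    path = Path(path)
    start = _read_start_line(path)
    df = _read_csv(path, _TRACE5_COLS, skiprows=1)
    if chick_id is None:
        chick_id = path.name.removesuffix("_trace5.csv")
    return SensorTrace(chick_id=chick_id, df=df[_TRACE5_COLS], start_utc=start)


# ---------------------------------------------------------------------------
# bout tables


def write_bouts(bouts: BoutSet, path: Path) -> None:
    """Write a bout table (chick_id,start_s,end_s,label), 1 ms precision."""
    df = pd.DataFrame(
        [
            {
                "chick_id": bouts.chick_id,
                "start_s": b.start_s,
                "end_s": b.end_s,
                "label": b.label,
            }
            for b in bouts
        ],
        columns=["chick_id", "start_s", "end_s", "label"],
    )
    df.to_csv(path, index=False, float_format="%.3f")


def read_bouts(path: Path, chick_id: str | None = None) -> BoutSet:
    df = _read_csv(Path(path), ["chick_id", "start_s", "end_s", "label"])
    if len(df) == 0:
        return BoutSet(chick_id=chick_id or "", bouts=[])
    ids = df["chick_id"].astype(str).unique()
    if chick_id is None:
        if len(ids) != 1:
            raise FormatError(f"bout table mixes chick ids {list(ids)}")
        chick_id = str(ids[0])
    else:
        df = df[df["chick_id"].astype(str) == chick_id]
    bouts = [
        Bout(float(r["start_s"]), float(r["end_s"]), str(r["label"]),
             provenance="file")
        for _, r in df.iterrows()
    ]
    bouts.sort(key=lambda b: b.start_s)
    return BoutSet(chick_id=chick_id, bouts=bouts)  # validates overlap
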