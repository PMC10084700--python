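"""Rule chain turning candidate low-activity bouts into brooding bouts.

A low-activity bout is only brooding if the sensors agree with what real
brooding looks like: during daylight the chick's back is pressed under the
parent, so the light level must drop below 50 lx for at least part of the
bout (stays in plant shade read 200–2,000 lx and are rejected); the on-body
temperature should warm toward the parent at bout start and relax back
after it, which is used to fine-tune bout boundaries; and bouts or breaks
of up to 20 s are treated as positioning artifacts and pruned.

Chicks whose growing feathers cover the light sensor (≈ 65 g) are flagged
and excluded from downstream summaries, since daytime brooding becomes
undetectable for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .accel import SensorTrace
from .bouts import Bout, BoutSet
from .config import PipelineConfig
from .io import ChickRecord

PROV_FINAL = "final"
_PROV_SKIP_ADJUST = {"adjusted", PROV_FINAL}


@dataclass
class TempDiffStats:
    """Per-chick medians of consecutive-bin on-body temperature differences."""

    chick_id: str
    median_diff_brooding: float  # °C per 5-s bin
    median_diff_active: float
    n_brooding: int
    n_active: int
    available: bool


# ---------------------------------------------------------------------------
# helpers


def _bin_labels(bouts: BoutSet, t5: np.ndarray) -> np.ndarray:
    """Label of the bout covering each bin start (empty string if none)."""
    labels = np.full(len(t5), "", dtype=object)
    for b in bouts:
        mask = (t5 >= b.start_s - 1e-9) & (t5 < b.end_s - 1e-9)
        labels[mask] = b.label
    return labels


def _bout_mask(b: Bout, t5: np.ndarray) -> np.ndarray:
    return (t5 >= b.start_s - 1e-9) & (t5 < b.end_s - 1e-9)


# ---------------------------------------------------------------------------
# rules


def apply_light_rule(
    cands: BoutSet,
    trace: SensorTrace,
    lx_thresh: float = 50.0,
    night_elev_deg: float = -6.0,
    min_dark_bins: int = 1,
) -> BoutSet:
    """Reject daylight low-activity bouts that never get dark enough.

    A candidate brooding bout that overlaps daylight (any bin with sun
    elevation ≥ −6°) keeps its label only if at least ``min_dark_bins`` of
    its bins read below ``lx_thresh`` lx; otherwise it becomes
    ``other_inactive``.  Bouts entirely in the night are exempt.
    """
    light = trace.light5
    if np.all(~np.isfinite(light)):
        raise ValueError("light channel missing; light rule cannot be evaluated")
    t5, elev = trace.t5, trace.sun_elev
    out = []
    for b in cands:
        if b.label != "brooding":
            out.append(b)
            continue
        m = _bout_mask(b, t5)
        daylight = m & (elev >= night_elev_deg)
        if daylight.any():
            dark = m & np.isfinite(light) & (light < lx_thresh)
            if int(dark.sum()) < min_dark_bins:
                b = replace(b, label="other_inactive", provenance="light_rule")
        out.append(b)
    return cands.with_bouts(out)


def temp_diff_stats(
    cands: BoutSet, trace: SensorTrace, min_statebins: int = 10
) -> TempDiffStats:
    """Median consecutive-bin temperature change within brooding / active bouts.

    The difference into bin *i* (tbody5[i] − tbody5[i−1]) is pooled under a
    label when both bins lie in the same bout.  With fewer than
    ``min_statebins`` differences in either pool the stats are flagged
    unavailable and boundary adjustment is skipped for the chick.
    """
    t5 = trace.t5
    tb = trace.tbody5
    diffs = np.diff(tb)
    labels = _bin_labels(cands, t5)
    same_bout = labels[1:] == labels[:-1]
    pools = {}
    for lab in ("brooding", "active"):
        sel = same_bout & (labels[1:] == lab) & np.isfinite(diffs)
        pools[lab] = diffs[sel]
    n_b, n_a = len(pools["brooding"]), len(pools["active"])
    if n_b < min_statebins or n_a < min_statebins:
        warnings.warn(
            f"chick {cands.chick_id}: only {n_b} brooding / {n_a} active "
            "temperature differences; boundary adjustment skipped",
            stacklevel=2,
        )
        return TempDiffStats(cands.chick_id, np.nan, np.nan, n_b, n_a, False)
    return TempDiffStats(
        cands.chick_id,
        float(np.median(pools["brooding"])),
        float(np.median(pools["active"])),
        n_b,
        n_a,
        True,
    )


def adjust_boundaries(
    cands: BoutSet,
    trace: SensorTrace,
    stats: TempDiffStats,
    cfg: PipelineConfig | None = None,
) -> BoutSet:
    """Shift brooding bout starts to warming onset and ends to cooling onset.

    The start moves forward to the earliest bin — searching from the bout
    start to the bout midpoint — where the temperature difference exceeds
    the chick's brooding median and keeps exceeding it for
    ``cfg.adjust_sustain_bins`` consecutive bins (sustained warming onset:
    a chick often settles before the parent actually covers it, and the
    sustain requirement keeps single-bin sensor noise from triggering).
    The end (start of the following break) moves to the first bin after
    the low-activity period, searching forward from the bout end to the
    midpoint of the following active interval, where the difference
    crosses the active median (by default falls below it, again sustained:
    the chick keeps warm until it actually leaves the parent, so cooling
    onset marks the true end even when activity rises earlier).  Neighbors
    are resized so the intervals never invert or overlap; bouts already
    adjusted once are left alone.
    """
    cfg = cfg or PipelineConfig()
    if not stats.available:
        return cands
    t5 = trace.t5
    tb = trace.tbody5
    if len(t5) < 2:
        return cands
    diffs = np.concatenate([[np.nan], np.diff(tb)])  # diff into bin i
    k = max(int(cfg.adjust_sustain_bins), 1)

    def _sustained(qualify: np.ndarray) -> np.ndarray:
        """True at j when qualify[j : j + k] holds everywhere."""
        q = qualify.astype(float)
        if len(q) < k:
            return np.zeros_like(qualify, dtype=bool)
        runs = np.convolve(q, np.ones(k), mode="full")[k - 1 : len(q) + k - 1]
        ok = np.zeros_like(qualify, dtype=bool)
        ok[: len(q) - k + 1] = runs[: len(q) - k + 1] == k
        return ok

    warm_ok = _sustained(diffs > stats.median_diff_brooding)
    if cfg.break_direction == "below":
        cool_ok = _sustained(diffs < stats.median_diff_active)
    else:
        cool_ok = _sustained(diffs > stats.median_diff_active)

    bouts = list(cands.bouts)
    for i, b in enumerate(bouts):
        if b.label != "brooding" or b.provenance in _PROV_SKIP_ADJUST:
            continue
        mid_bout = (b.start_s + b.end_s) / 2.0
        prev_b = bouts[i - 1] if i > 0 else None

        # --- start: earliest sustained-warming bin inside the first half
        sel = np.flatnonzero((t5 >= b.start_s) & (t5 < mid_bout) & warm_ok)
        new_start = b.start_s
        if sel.size:
            new_start = float(t5[sel[0]])

        # --- end: first bin after the low-activity period crossing the
        # active median (scan forward from the bout end)
        next_b = bouts[i + 1] if i + 1 < len(bouts) else None
        next_active = next(
            (bouts[j] for j in range(i + 1, len(bouts)) if bouts[j].label == "active"),
            None,
        )
        win_hi = (
            (next_active.start_s + next_active.end_s) / 2.0
            if next_active is not None
            else b.end_s
        )
        if next_b is not None:
            win_hi = min(win_hi, next_b.end_s - trace.bin_s)
        sel = np.flatnonzero((t5 >= b.end_s) & (t5 < win_hi) & cool_ok)
        new_end = b.end_s
        if sel.size:
            new_end = float(t5[sel[0]])

        if new_end <= new_start:  # degenerate adjustment: keep original bout
            new_start, new_end = b.start_s, b.end_s
        bouts[i] = Bout(new_start, new_end, b.label, "adjusted")
        # resize neighbors to keep the partition well-formed
        if prev_b is not None and abs(prev_b.end_s - b.start_s) < 1e-9:
            if new_start > prev_b.start_s:
                bouts[i - 1] = replace(prev_b, end_s=new_start)
        if next_b is not None and abs(next_b.start_s - b.end_s) < 1e-9:
            if new_end < next_b.end_s:
                bouts[i + 1] = replace(next_b, start_s=new_end)

    return cands.with_bouts(bouts)


def _coalesce(bouts: list[Bout]) -> list[Bout]:
    out: list[Bout] = []
    for b in bouts:
        if (
            out
            and out[-1].label == b.label
            and abs(out[-1].end_s - b.start_s) < 1e-9
        ):
            out[-1] = replace(out[-1], end_s=b.end_s)
        else:
            out.append(b)
    return out


def drop_short(bouts: BoutSet, min_s: float = 20.0) -> BoutSet:
    """Prune brooding bouts and within-brooding breaks of up to ``min_s``.

    Breaks no longer than ``min_s`` between two brooding bouts are merged
    into one bout; brooding bouts no longer than ``min_s`` are relabeled to
    their flanking label.  Merges run before drops and the pair repeats to
    a fixed point ("up to 20 s" read inclusively).
    """
    cur = list(bouts.bouts)
    while True:
        changed = False
        # merge short breaks flanked by brooding on both sides
        for i, b in enumerate(cur):
            if b.label == "brooding":
                continue
            if not (0 < i < len(cur) - 1):
                continue
            if (
                b.duration_s <= min_s + 1e-9
                and cur[i - 1].label == "brooding"
                and cur[i + 1].label == "brooding"
                and abs(cur[i - 1].end_s - b.start_s) < 1e-9
                and abs(b.end_s - cur[i + 1].start_s) < 1e-9
            ):
                cur[i] = replace(b, label="brooding", provenance="merged")
                changed = True
        cur = _coalesce(cur)
        # drop short brooding bouts into a flanking label
        for i, b in enumerate(cur):
            if b.label != "brooding" or b.duration_s > min_s + 1e-9:
                continue
            if i > 0:
                new_label = cur[i - 1].label
            elif i + 1 < len(cur):
                new_label = cur[i + 1].label
            else:
                new_label = "other_inactive"
            cur[i] = replace(b, label=new_label, provenance="dropped")
            changed = True
        cur = _coalesce(cur)
        if not changed:
            break
    return bouts.with_bouts(cur)


def flag_feathered(chick: ChickRecord, mass_thresh_g: float = 65.0) -> bool:
    """True when feather growth likely covers the light sensor (~65 g)."""
    return chick.mass_start >= mass_thresh_g or chick.mass_end >= mass_thresh_g


def qc_report(final: BoutSet, trace: SensorTrace) -> list[str]:
    """Plain-text heuristics flagging bouts worth a human look.

    Replaces the manual-inspection step: long daylight brooding bouts whose
    temperature never rises above ambient, or bouts with interior light
    spikes, are listed — never silently corrected.
    """
    msgs = []
    t5 = trace.t5
    for b in final.select("brooding"):
        m = _bout_mask(b, t5)
        if not m.any() or b.duration_s < 300:
            continue
        tb = trace.tbody5[m]
        ta = trace.df["tamb5"].to_numpy(float)[m]
        if np.isfinite(tb).any() and np.isfinite(ta).any():
            if np.nanmedian(tb) < np.nanmedian(ta) - 2.0:
                msgs.append(
                    f"bout {b.start_s:.0f}-{b.end_s:.0f}s: on-body temperature "
                    "stays well below ambient during claimed brooding"
                )
        light = trace.light5[m]
        if np.isfinite(light).any() and np.nanmax(light) > 5000:
            msgs.append(
                f"bout {b.start_s:.0f}-{b.end_s:.0f}s: interior light spike "
                f"({np.nanmax(light):.0f} lx) inside brooding bout"
            )
    return msgs


def run_postprocess(
    cands: BoutSet,
    trace: SensorTrace,
    chick: ChickRecord | None = None,
    cfg: PipelineConfig | None = None,
) -> BoutSet:
    """Full rule chain: light rule → temp-diff stats → boundary shift → prune.

    A second light-rule pass after pruning guarantees that every finalized
    daylight brooding bout still contains a dark bin even when its
    boundaries moved.  The result is a fixed point: running the chain on
    its own output changes nothing.
    """
    cfg = cfg or PipelineConfig()
    step = apply_light_rule(
        cands, trace, cfg.lx_thresh, cfg.night_elev_deg, cfg.min_dark_bins
    )
    stats = temp_diff_stats(step, trace, cfg.min_statebins)
    step = adjust_boundaries(step, trace, stats, cfg)
    step = drop_short(step, cfg.short_s)
    step = apply_light_rule(
        step, trace, cfg.lx_thresh, cfg.night_elev_deg, cfg.min_dark_bins
    )
    step = drop_short(step, cfg.short_s)
    final = step.with_bouts(
        [replace(b, provenance=PROV_FINAL) for b in step.bouts]
    )
    return final
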