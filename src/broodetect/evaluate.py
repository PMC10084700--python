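"""Score pipeline output against simulator ground truth.

Scoring happens on the 5-s analysis grid (detection cannot be finer):
truth states are downsampled to each bin by majority, with ties counted as
brooding so recall is scored conservatively.  Bout-level matching is
one-to-one greedy by descending intersection-over-union.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .accel import SensorTrace
from .bouts import Bout, BoutSet
from .postprocess import _bin_labels
from .synth import SimTruth


@dataclass
class EvalReport:
    chick_id: str
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    specificity: float
    bout_precision: float
    bout_recall: float
    bout_f1: float
    median_start_error_s: float
    median_end_error_s: float
    rate_error: float  # estimated − true brooding proportion

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------


def truth_brooding_bins(truth: SimTruth, t5: np.ndarray, grid_s: float = 5.0
                        ) -> np.ndarray:
    """Majority-downsampled truth (brooding vs not) per scoring bin."""
    state = truth.state_per_s
    out = np.zeros(len(t5), dtype=bool)
    n = len(state)
    for k, t in enumerate(t5):
        i0 = int(round(t))
        i1 = min(int(round(t + grid_s)), n)
        if i0 >= n or i1 <= i0:
            continue
        frac = np.mean(state[i0:i1] == "brooding")
        out[k] = frac >= 0.5  # ties count as brooding
    return out


def sample_confusion(
    pred: BoutSet, truth: SimTruth, t5: np.ndarray, grid_s: float = 5.0
) -> dict[str, int]:
    """Per-bin brooding/non-brooding confusion counts on the scoring grid."""
    if pred.chick_id and truth.chick_id and pred.chick_id != truth.chick_id:
        raise ValueError(
            f"prediction is for {pred.chick_id!r}, truth for {truth.chick_id!r}"
        )
    if len(t5) and (t5[-1] + grid_s) > len(truth.state_per_s) + grid_s:
        raise ValueError("scoring grid extends beyond the truth timeline")
    truth_b = truth_brooding_bins(truth, t5, grid_s)
    pred_b = _bin_labels(pred, np.asarray(t5, dtype=float)) == "brooding"
    return {
        "tp": int(np.sum(pred_b & truth_b)),
        "fp": int(np.sum(pred_b & ~truth_b)),
        "fn": int(np.sum(~pred_b & truth_b)),
        "tn": int(np.sum(~pred_b & ~truth_b)),
    }


def confusion_metrics(c: dict[str, int]) -> dict[str, float]:
    tp, fp, fn, tn = c["tp"], c["fp"], c["fn"], c["tn"]
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    return {
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
        "balanced_accuracy": (sens + spec) / 2.0,
        "precision": tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0),
        "recall": sens,
        "specificity": spec,
    }


# ---------------------------------------------------------------------------


def _iou(a: Bout, b: Bout) -> float:
    inter = max(0.0, min(a.end_s, b.end_s) - max(a.start_s, b.start_s))
    union = max(a.end_s, b.end_s) - min(a.start_s, b.start_s)
    return inter / union if union > 0 else 0.0


def match_bouts(
    pred: list[Bout], truth: list[Bout], min_overlap: float = 0.5
) -> list[tuple[Bout, Bout]]:
    """One-to-one greedy matching by descending intersection/union."""
    cand = [
        (_iou(p, t), ip, it)
        for ip, p in enumerate(pred)
        for it, t in enumerate(truth)
        if _iou(p, t) >= min_overlap
    ]
    cand.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, ip, it in cand:
        if ip in used_p or it in used_t:
            continue
        used_p.add(ip)
        used_t.add(it)
        pairs.append((pred[ip], truth[it]))
    return pairs


def bout_f1(
    pred: BoutSet,
    truth_bouts: BoutSet,
    min_overlap: float = 0.5,
    window: tuple[float, float] | None = None,
) -> dict:
    """Bout-level precision/recall/F1 for brooding bouts.

    ``window`` restricts both sets to the scored interval (truth bouts are
    clipped to it, so edge-trimmed predictions are not penalized).
    """
    p = pred.select("brooding")
    t = truth_bouts.select("brooding")
    if window is not None:
        lo, hi = window
        t = [
            Bout(max(b.start_s, lo), min(b.end_s, hi), b.label, b.provenance)
            for b in t
            if b.end_s > lo and b.start_s < hi
        ]
        p = [
            Bout(max(b.start_s, lo), min(b.end_s, hi), b.label, b.provenance)
            for b in p
            if b.end_s > lo and b.start_s < hi
        ]
    pairs = match_bouts(p, t, min_overlap)
    precision = len(pairs) / len(p) if p else (1.0 if not t else 0.0)
    recall = len(pairs) / len(t) if t else 1.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "matches": pairs,
    }


def boundary_error(pairs: list[tuple[Bout, Bout]]) -> dict[str, float]:
    """Median absolute start/end offsets of matched bout pairs, seconds."""
    if not pairs:
        return {"median_start_error_s": np.nan, "median_end_error_s": np.nan,
                "available": False}
    starts = [abs(p.start_s - t.start_s) for p, t in pairs]
    ends = [abs(p.end_s - t.end_s) for p, t in pairs]
    return {
        "median_start_error_s": float(np.median(starts)),
        "median_end_error_s": float(np.median(ends)),
        "available": True,
    }


# ---------------------------------------------------------------------------


def evaluate_chick(pred: BoutSet, truth: SimTruth, trace: SensorTrace
                   ) -> EvalReport:
    """Full per-chick scorecard on the trimmed trace."""
    t5 = trace.t5
    conf = sample_confusion(pred, truth, t5, trace.bin_s)
    m = confusion_metrics(conf)
    window = (float(t5[0]), float(t5[-1] + trace.bin_s)) if len(t5) else (0.0, 0.0)
    bf = bout_f1(pred, truth.bouts, 0.5, window)
    be = boundary_error(bf["matches"])
    truth_b = truth_brooding_bins(truth, t5, trace.bin_s)
    true_prop = float(np.mean(truth_b)) if len(t5) else np.nan
    pred_b = _bin_labels(pred, t5) == "brooding"
    est_prop = float(np.mean(pred_b)) if len(t5) else np.nan
    return EvalReport(
        chick_id=pred.chick_id or truth.chick_id,
        accuracy=m["accuracy"],
        balanced_accuracy=m["balanced_accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        specificity=m["specificity"],
        bout_precision=bf["precision"],
        bout_recall=bf["recall"],
        bout_f1=bf["f1"],
        median_start_error_s=be["median_start_error_s"],
        median_end_error_s=be["median_end_error_s"],
        rate_error=est_prop - true_prop,
    )


def cohort_summary(reports: list[EvalReport]) -> dict[str, float]:
    df = pd.DataFrame([r.as_dict() for r in reports])
    return {
        "n_chicks": len(reports),
        "balanced_accuracy_median": float(df["balanced_accuracy"].median()),
        "balanced_accuracy_min": float(df["balanced_accuracy"].min()),
        "bout_f1_median": float(df["bout_f1"].median()),
        "bout_f1_min": float(df["bout_f1"].min()),
        "rate_abs_error_median": float(df["rate_error"].abs().median()),
        "start_error_median_s": float(df["median_start_error_s"].median()),
        "end_error_median_s": float(df["median_end_error_s"].median()),
    }


def load_truth(path: Path) -> dict[str, SimTruth]:
    """Rebuild per-chick SimTruth objects from a cohort's truth.csv."""
    from .synth import SimConfig, _true_bouts

    df = pd.read_csv(path)
    out = {}
    for cid, grp in df.groupby("chick_id"):
        grp = grp.sort_values("start_s")
        n = int(grp["end_s"].max())
        state = np.empty(n, dtype=object)
        for _, r in grp.iterrows():
            state[int(r["start_s"]) : int(r["end_s"])] = r["state"]
        out[str(cid)] = SimTruth(
            chick_id=str(cid),
            state_per_s=state,
            bouts=_true_bouts(str(cid), state),
            brooding_prop=float(np.mean(state == "brooding")),
            config=SimConfig(),
        )
    return out
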