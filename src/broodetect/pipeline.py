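"""High-level orchestration: raw recording → finalized brooding bouts."""

from __future__ import annotations

import numpy as np

from .accel import SensorTrace
from .bouts import BoutSet
from .config import PipelineConfig
from .hmm import fit_two_state, states_to_bouts, viterbi_decode
from .io import ChickRecord
from .postprocess import run_postprocess


def detect_chick(
    trace: SensorTrace,
    chick: ChickRecord | None = None,
    cfg: PipelineConfig | None = None,
    seed: int = 1,
) -> BoutSet:
    """Segment one chick's trimmed 5-s trace into finalized brooding bouts.

    Fits the per-chick two-state HMM on ODBA, decodes the Viterbi path,
    converts nonactive runs into candidate bouts, and applies the
    post-processing rule chain (light, temperature boundaries, pruning).
    """
    cfg = cfg or PipelineConfig()
    odba5 = np.nan_to_num(trace.odba5, nan=0.0)
    params = fit_two_state(
        odba5,
        seed=seed,
        eps_g=cfg.hmm_eps_g,
        tol=cfg.hmm_tol,
        max_iter=cfg.hmm_max_iter,
    )
    path = viterbi_decode(params, odba5, t5=trace.t5)
    cands = states_to_bouts(path, chick_id=trace.chick_id, bin_s=trace.bin_s)
    return run_postprocess(cands, trace, chick, cfg)
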