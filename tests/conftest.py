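"""Shared fixtures: one small simulated chick reused across test modules."""

from datetime import timedelta

import numpy as np
import pytest

from broodetect import accel, pipeline, synth
from broodetect.io import ChickRecord


@pytest.fixture(scope="session")
def nl_sim():
    """12-h temperate-preset chick: raw recording, ambient, truth."""
    cfg = synth.nl_preset(duration_h=12.0, seed=11)
    raw, amb, truth = synth.simulate_chick(cfg, "nl01")
    chick = ChickRecord(
        "nl01", "f01", "NL", 30.0, 25.0, 30.0,
        raw.start_utc, raw.start_utc + timedelta(hours=12),
        cfg.lat, cfg.lon,
    )
    return raw, amb, truth, chick


@pytest.fixture(scope="session")
def nl_trace(nl_sim):
    raw, amb, truth, chick = nl_sim
    trace, params = accel.preprocess_chick(raw, amb, chick)
    return trace


@pytest.fixture(scope="session")
def nl_bouts(nl_trace, nl_sim):
    _, _, _, chick = nl_sim
    return pipeline.detect_chick(nl_trace, chick, seed=1)
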