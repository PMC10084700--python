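"""The brooding rule chain: light rule, boundary shifts, pruning."""

from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from broodetect import postprocess as pp
from broodetect.accel import SensorTrace
from broodetect.bouts import Bout, BoutSet
from broodetect.config import PipelineConfig
from broodetect.io import ChickRecord
from broodetect.postprocess import TempDiffStats

START = datetime(2019, 5, 10, 0, 0, tzinfo=timezone.utc)


def make_trace(n_bins, odba=0.1, tbody=30.0, light=10.0, elev=20.0):
    as_arr = lambda v: np.full(n_bins, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)
    df = pd.DataFrame(
        {
            "t5": np.arange(n_bins) * 5.0,
            "odba5": as_arr(odba),
            "tbody5": as_arr(tbody),
            "light5": as_arr(light),
            "tamb5": 15.0,
            "sun_elev": as_arr(elev),
            "n_valid": 125,
        }
    )
    return SensorTrace("c", df, START)


class TestLightRule:
    def test_bright_daylight_bout_rejected(self):
        trace = make_trace(20, light=300.0, elev=30.0)
        cands = BoutSet("c", [Bout(0.0, 100.0, "brooding")])
        out = pp.apply_light_rule(cands, trace)
        assert out.bouts[0].label == "other_inactive"

    def test_night_bout_exempt(self):
        trace = make_trace(20, light=300.0, elev=-10.0)
        cands = BoutSet("c", [Bout(0.0, 100.0, "brooding")])
        out = pp.apply_light_rule(cands, trace)
        assert out.bouts[0].label == "brooding"

    def test_single_dark_bin_retains_bout(self):
        light = np.full(20, 5000.0)
        light[7] = 10.0
        trace = make_trace(20, light=light, elev=30.0)
        cands = BoutSet("c", [Bout(0.0, 100.0, "brooding")])
        out = pp.apply_light_rule(cands, trace)
        assert out.bouts[0].label == "brooding"

    def test_missing_light_channel_is_an_error(self):
        trace = make_trace(20, light=np.nan, elev=30.0)
        cands = BoutSet("c", [Bout(0.0, 100.0, "brooding")])
        with pytest.raises(ValueError, match="light"):
            pp.apply_light_rule(cands, trace)

    def test_daylight_brooding_never_increases(self, nl_trace, nl_bouts):
        day = nl_trace.sun_elev >= -6.0
        t5 = nl_trace.t5

        def day_brood_s(bs):
            lab = pp._bin_labels(bs, t5)
            return float(np.sum(day & (lab == "brooding"))) * 5.0

        from broodetect.hmm import fit_two_state, states_to_bouts, viterbi_decode

        odba5 = np.nan_to_num(nl_trace.odba5)
        params = fit_two_state(odba5, seed=1)
        cands = states_to_bouts(
            viterbi_decode(params, odba5, t5=t5), chick_id="nl01"
        )
        after = pp.apply_light_rule(cands, nl_trace)
        assert day_brood_s(after) <= day_brood_s(cands)


class TestTempDiffStats:
    def test_constant_temperature_gives_zero_medians(self):
        trace = make_trace(60, tbody=30.0)
        cands = BoutSet(
            "c", [Bout(0.0, 150.0, "brooding"), Bout(150.0, 300.0, "active")]
        )
        s = pp.temp_diff_stats(cands, trace)
        assert s.available
        assert s.median_diff_brooding == 0.0
        assert s.median_diff_active == 0.0

    def test_constructed_slopes_recovered(self):
        tbody = np.concatenate([30 + 0.2 * np.arange(30), 36 - 0.1 * np.arange(30)])
        trace = make_trace(60, tbody=tbody)
        cands = BoutSet(
            "c", [Bout(0.0, 150.0, "brooding"), Bout(150.0, 300.0, "active")]
        )
        s = pp.temp_diff_stats(cands, trace)
        assert s.median_diff_brooding == pytest.approx(0.2)
        assert s.median_diff_active == pytest.approx(-0.1)

    def test_pooled_medians_match_group_by_oracle(self, nl_trace, nl_bouts):
        s = pp.temp_diff_stats(nl_bouts, nl_trace)
        t5, tb = nl_trace.t5, nl_trace.tbody5
        labels = pp._bin_labels(nl_bouts, t5)
        diffs = np.diff(tb)
        pool = {
            lab: [
                diffs[i - 1]
                for i in range(1, len(t5))
                if labels[i] == lab and labels[i - 1] == lab
            ]
            for lab in ("brooding", "active")
        }
        assert s.median_diff_brooding == pytest.approx(np.median(pool["brooding"]))
        assert s.median_diff_active == pytest.approx(np.median(pool["active"]))

    def test_insufficient_bins_marks_unavailable(self):
        trace = make_trace(10)
        cands = BoutSet("c", [Bout(0.0, 25.0, "brooding"), Bout(25.0, 50.0, "active")])
        with pytest.warns(UserWarning, match="skipped"):
            s = pp.temp_diff_stats(cands, trace)
        assert not s.available


class TestAdjustBoundaries:
    def _stats(self):
        return TempDiffStats("c", 0.01, -0.01, 100, 100, True)

    def test_bout_at_warming_onset_unchanged(self):
        # warming starts exactly at the bout start
        tbody = np.concatenate(
            [np.full(20, 15.0), 15 + 0.5 * np.arange(1, 21), np.full(60, 25.0)]
        )
        trace = make_trace(100, tbody=tbody)
        cands = BoutSet(
            "c",
            [Bout(0.0, 100.0, "active"), Bout(100.0, 400.0, "brooding"),
             Bout(400.0, 500.0, "active")],
        )
        out = pp.adjust_boundaries(cands, trace, self._stats())
        b = out.select("brooding")[0]
        assert b.start_s == 100.0

    def test_inactivity_before_contact_start_moved_forward(self):
        # chick settles at t=100 s but warming (contact) only begins at 160 s
        tbody = np.full(100, 15.0)
        tbody[32:42] = 15.0 + 0.5 * np.arange(1, 11)  # bins 160–210 s warm
        tbody[42:80] = tbody[41]
        tbody[80:90] = tbody[41] - 0.5 * np.arange(1, 11)  # cooling at 400 s
        tbody[90:] = tbody[89]
        trace = make_trace(100, tbody=tbody)
        cands = BoutSet(
            "c",
            [Bout(0.0, 100.0, "active"), Bout(100.0, 400.0, "brooding"),
             Bout(400.0, 500.0, "active")],
        )
        out = pp.adjust_boundaries(cands, trace, self._stats())
        b = out.select("brooding")[0]
        assert abs(b.start_s - 160.0) <= 5.0  # within one bin of true contact
        assert abs(b.end_s - 400.0) <= 5.0
        # partition stays well-formed
        out.validate()
        assert out.bouts[0].end_s == b.start_s

    def test_no_qualifying_bin_leaves_bouts_identical(self):
        trace = make_trace(100, tbody=30.0)
        stats = TempDiffStats("c", 0.05, -0.05, 100, 100, True)
        cands = BoutSet(
            "c",
            [Bout(0.0, 100.0, "active"), Bout(100.0, 400.0, "brooding"),
             Bout(400.0, 500.0, "active")],
        )
        out = pp.adjust_boundaries(cands, trace, stats)
        assert [(b.start_s, b.end_s) for b in out] == [
            (0.0, 100.0), (100.0, 400.0), (400.0, 500.0)
        ]

    def test_unavailable_stats_is_a_no_op(self):
        trace = make_trace(50)
        cands = BoutSet("c", [Bout(0.0, 250.0, "brooding")])
        stats = TempDiffStats("c", np.nan, np.nan, 0, 0, False)
        assert pp.adjust_boundaries(cands, trace, stats) is cands


class TestDropShort:
    def test_short_bout_between_active_removed(self):
        bs = BoutSet(
            "c",
            [Bout(0.0, 300.0, "active"), Bout(300.0, 315.0, "brooding"),
             Bout(315.0, 600.0, "active")],
        )
        out = pp.drop_short(bs, 20.0)
        assert out.select("brooding") == []
        assert len(out) == 1  # coalesced into one active interval

    def test_short_gap_merges_bouts(self):
        bs = BoutSet(
            "c",
            [Bout(0.0, 600.0, "brooding"), Bout(600.0, 610.0, "active"),
             Bout(610.0, 1210.0, "brooding")],
        )
        out = pp.drop_short(bs, 20.0)
        brood = out.select("brooding")
        assert len(brood) == 1
        assert brood[0].duration_s == 1210.0

    def test_exactly_20s_bout_removed(self):
        bs = BoutSet(
            "c",
            [Bout(0.0, 100.0, "active"), Bout(100.0, 120.0, "brooding"),
             Bout(120.0, 300.0, "active")],
        )
        assert pp.drop_short(bs, 20.0).select("brooding") == []

    def test_cascading_merge_then_fixed_point(self):
        # merging the 10 s gap creates one bout; nothing further changes
        bs = BoutSet(
            "c",
            [Bout(0.0, 15.0, "brooding"), Bout(15.0, 25.0, "active"),
             Bout(25.0, 40.0, "brooding"), Bout(40.0, 400.0, "active")],
        )
        out = pp.drop_short(bs, 20.0)
        brood = out.select("brooding")
        assert len(brood) == 1 and brood[0].duration_s == 40.0
        again = pp.drop_short(out, 20.0)
        assert [(b.start_s, b.end_s, b.label) for b in again] == [
            (b.start_s, b.end_s, b.label) for b in out
        ]


class TestFlagFeathered:
    @pytest.mark.parametrize(
        "mass,expected", [(70.0, True), (30.0, False), (64.9, False), (65.0, True)]
    )
    def test_mass_threshold(self, mass, expected):
        chick = ChickRecord(
            "c", "f", "NL", 30.0, mass, mass, START,
            datetime(2019, 5, 12, tzinfo=timezone.utc), 48.99, 14.38,
        )
        assert pp.flag_feathered(chick, 65.0) is expected


class TestRunPostprocess:
    def test_all_active_candidates_give_no_brooding(self):
        trace = make_trace(200)
        cands = BoutSet("c", [Bout(0.0, 1000.0, "active")])
        out = pp.run_postprocess(cands, trace)
        assert out.select("brooding") == []

    def test_finalized_invariants(self, nl_trace, nl_bouts):
        brood = nl_bouts.select("brooding")
        assert all(b.duration_s > 20.0 for b in brood)
        for a, b in zip(brood, brood[1:]):
            assert b.start_s - a.end_s > 20.0
        # every daylight brooding bout has a dark bin
        t5, elev, light = nl_trace.t5, nl_trace.sun_elev, nl_trace.light5
        for b in brood:
            m = (t5 >= b.start_s) & (t5 < b.end_s)
            if np.any(m & (elev >= -6.0)):
                assert np.any(m & (light < 50.0))

    def test_idempotent_on_own_output(self, nl_trace, nl_bouts):
        again = pp.run_postprocess(nl_bouts, nl_trace)
        assert len(again) == len(nl_bouts)
        for a, b in zip(again, nl_bouts):
            assert a.start_s == b.start_s
            assert a.end_s == b.end_s
            assert a.label == b.label
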