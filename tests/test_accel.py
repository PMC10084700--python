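"""Filtering, ODBA, autocalibration and 5-s aggregation."""

from datetime import datetime, timezone

import numpy as np
import pytest

from broodetect import accel
from broodetect.config import PipelineConfig
from broodetect.io import AmbientSeries, ChickRecord, RawTrace

START = datetime(2019, 5, 10, 6, 0, tzinfo=timezone.utc)


def brute_force_median(x: np.ndarray, w: int) -> np.ndarray:
    """Naive O(n·w) centered moving median with truncated edges."""
    n = len(x)
    h = w // 2
    return np.array([np.median(x[max(0, i - h) : min(n, i + h + 1)]) for i in range(n)])


def brute_force_odba(ax, ay, az, fs=25.0):
    out = np.zeros(len(ax))
    for x in (ax, ay, az):
        w_hp = int(round(fs / 0.2)) | 1
        w_lp = int(round(fs / 2.0)) | 1
        dyn = x - brute_force_median(x, w_hp)
        out += np.abs(brute_force_median(dyn, w_lp))
    return out


class TestMedianFilter:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.7)
        np.testing.assert_array_equal(accel.median_filter(x, 2.0, 25.0), x)

    def test_single_spike_removed(self):
        x = np.full(200, 1.0)
        x[100] = 50.0
        y = accel.median_filter(x, 2.0, 25.0)
        assert y[100] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300)
        got = accel.median_filter(x, 5.0, 25.0)  # w = 5
        np.testing.assert_allclose(got, brute_force_median(x, 5), atol=1e-12)

    def test_window_forced_odd(self):
        # fs/fc = 10 → window 11; output at interior index is an 11-median
        x = np.arange(100, dtype=float)
        y = accel.median_filter(x, 2.5, 25.0)
        assert y[50] == np.median(x[45:56])

    def test_short_series_truncated_window(self):
        x = np.array([5.0, 1.0, 3.0])
        y = accel.median_filter(x, 0.2, 25.0)  # window 125 ≫ n
        assert y[1] == 3.0

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            accel.median_filter(np.zeros(10), 13.0, 25.0)


class TestOdba:
    def _raw(self, ax, ay, az):
        n = len(ax)
        n_s = n // 25
        return RawTrace(
            "c", np.arange(n) / 25.0, ax, ay, az,
            np.arange(n_s, dtype=float), np.full(n_s, 30.0), np.full(n_s, 10.0),
            START,
        )

    def test_motionless_trace_exactly_zero(self):
        n = 25 * 120
        raw = self._raw(np.full(n, 0.1), np.full(n, -0.2), np.full(n, 0.97))
        odba = accel.compute_odba(raw)
        assert np.all(odba.odba == 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        n = 25 * 60
        raw = self._raw(
            rng.normal(0, 0.2, n), rng.normal(0, 0.2, n), 1 + rng.normal(0, 0.2, n)
        )
        got = accel.compute_odba(raw).odba
        want = brute_force_odba(raw.ax, raw.ay, raw.az)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_out_of_band_sine_suppressed_in_band_passes(self):
        # the 2 Hz moving median (window 13) spans 2.6 periods of a 5 Hz
        # sine and cancels it; a 1 Hz sine passes the chain
        n = 25 * 60
        t = np.arange(n) / 25.0
        zeros = np.zeros(n)
        hi = self._raw(0.5 * np.sin(2 * np.pi * 5.0 * t), zeros, zeros + 1)
        lo = self._raw(0.5 * np.sin(2 * np.pi * 1.0 * t), zeros, zeros + 1)
        interior = slice(200, -200)
        assert accel.compute_odba(hi).odba[interior].mean() < 1e-10
        mean_lo = accel.compute_odba(lo).odba[interior].mean()
        assert mean_lo == pytest.approx(0.2641, abs=0.01)  # frozen oracle value

    def test_shift_equivariance(self):
        rng = np.random.default_rng(9)
        n = 25 * 60
        x = rng.normal(0, 0.2, n)
        raw_a = self._raw(x, np.zeros(n), np.ones(n))
        shifted = np.roll(x, 50)
        raw_b = self._raw(shifted, np.zeros(n), np.ones(n))
        a = accel.compute_odba(raw_a).odba
        b = accel.compute_odba(raw_b).odba
        np.testing.assert_allclose(a[200:-300], b[250:-250], atol=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        n = 25 * 30
        raw = self._raw(*(rng.normal(0, 0.3, (3, n))))
        assert np.all(accel.compute_odba(raw).odba >= 0)


class TestAutocalibration:
    def test_static_windows_all_found_on_constant_trace(self):
        n = 25 * 100
        raw = RawTrace(
            "c", np.arange(n) / 25.0, np.zeros(n), np.zeros(n), np.ones(n),
            np.arange(100, dtype=float), np.full(100, 30.0), np.full(100, 5.0),
            START,
        )
        assert accel.find_static_windows(raw, 10.0, 0.013) == list(range(10))

    def test_white_noise_trace_has_no_static_windows(self):
        rng = np.random.default_rng(0)
        n = 25 * 100
        raw = RawTrace(
            "c", np.arange(n) / 25.0,
            rng.normal(0, 0.5, n), rng.normal(0, 0.5, n), rng.normal(0, 0.5, n),
            np.arange(100, dtype=float), np.full(100, 30.0), np.full(100, 5.0),
            START,
        )
        assert accel.find_static_windows(raw, 10.0, 0.013) == []

    def test_fixed_point_on_calibrated_vectors(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(30, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        p = accel.autocalibrate(v)
        assert p.converged
        np.testing.assert_allclose(p.offset, 0.0, atol=1e-8)
        np.testing.assert_allclose(p.gain, 1.0, atol=1e-8)

    def test_known_distortion_recovered(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(40, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        off = np.array([0.05, -0.03, 0.02])
        gain = np.array([1.02, 0.98, 1.01])
        p = accel.autocalibrate(v / gain + off)
        assert p.converged
        np.testing.assert_allclose(p.offset, off, atol=0.005)
        np.testing.assert_allclose(p.gain, gain, atol=0.005)

    @pytest.mark.parametrize("seed", range(50))
    def test_recovery_across_random_distortions(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(25, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        off = rng.uniform(-0.05, 0.05, 3)
        gain = rng.uniform(0.97, 1.03, 3)
        p = accel.autocalibrate(v / gain + off)
        assert p.converged
        assert np.max(np.abs(p.offset - off)) < 0.005
        assert np.max(np.abs(p.gain - gain)) < 0.005

    def test_single_orientation_gives_identity(self):
        rng = np.random.default_rng(4)
        v = np.tile([[0.0, 0.0, 1.0]], (20, 1)) + rng.normal(0, 0.002, (20, 3))
        p = accel.autocalibrate(v)
        assert not p.converged
        np.testing.assert_array_equal(p.offset, 0.0)
        np.testing.assert_array_equal(p.gain, 1.0)

    def test_too_few_windows_gives_identity(self):
        v = np.eye(3)
        p = accel.autocalibrate(v)
        assert not p.converged


class TestAggregation:
    def _inputs(self, n_s, odba_val=None, rng=None):
        n = n_s * 25
        odba = accel.OdbaSeries(
            t=np.arange(n) / 25.0,
            odba=(np.full(n, 0.2) if odba_val is None else odba_val),
        )
        if rng is not None:
            odba.odba = rng.exponential(0.1, n)
        raw = RawTrace(
            "c", odba.t, np.zeros(n), np.zeros(n), np.ones(n),
            np.arange(n_s, dtype=float), np.full(n_s, 31.0), np.full(n_s, 7.0),
            START,
        )
        t_amb = np.datetime64("2019-05-10T06:00:00", "ns") + np.arange(
            0, max(n_s, 600), 60
        ) * np.timedelta64(1, "s")
        amb = AmbientSeries(t_utc=t_amb, tamb=np.full(len(t_amb), 15.0))
        chick = ChickRecord(
            "c", "f", "NL", 30.0, 20.0, 25.0, START,
            datetime(2019, 5, 13, tzinfo=timezone.utc), 48.99, 14.38,
        )
        return odba, raw, amb, chick

    def test_constant_inputs_two_bins(self):
        odba, raw, amb, chick = self._inputs(10)
        tr = accel.aggregate_trace(odba, raw, amb, chick)
        assert len(tr) == 2
        np.testing.assert_allclose(tr.odba5, 0.2)
        np.testing.assert_allclose(tr.tbody5, 31.0)
        np.testing.assert_allclose(tr.df["tamb5"], 15.0)
        assert list(tr.df["n_valid"]) == [125, 125]

    def test_partial_final_bin(self):
        odba, raw, amb, chick = self._inputs(7)
        tr = accel.aggregate_trace(odba, raw, amb, chick)
        assert len(tr) == 2
        assert tr.df["n_valid"].iloc[1] < 125

    def test_bin_means_match_group_by_oracle(self):
        rng = np.random.default_rng(6)
        odba, raw, amb, chick = self._inputs(60, rng=rng)
        tr = accel.aggregate_trace(odba, raw, amb, chick)
        for k, t0 in enumerate(tr.t5):
            sel = (odba.t >= t0) & (odba.t < t0 + 5.0)
            assert tr.odba5[k] == pytest.approx(odba.odba[sel].mean(), abs=1e-12)

    def test_sample_count_conserved(self):
        rng = np.random.default_rng(7)
        odba, raw, amb, chick = self._inputs(63, rng=rng)
        tr = accel.aggregate_trace(odba, raw, amb, chick)
        assert tr.df["n_valid"].sum() == len(odba.t)

    def test_ambient_gap_leaves_missing(self):
        odba, raw, amb, chick = self._inputs(60)
        # one sample before, one 2 h later: a >1 h gap spans the whole trace
        t_amb = np.array(
            ["2019-05-10T05:59:00", "2019-05-10T08:00:00"], dtype="datetime64[ns]"
        )
        amb = AmbientSeries(t_utc=t_amb, tamb=np.array([10.0, 20.0]))
        with pytest.warns(UserWarning, match="ambient gap"):
            tr = accel.aggregate_trace(odba, raw, amb, chick)
        assert tr.df["tamb5"].isna().all()


class TestTrim:
    def _trace(self, hours):
        n = int(hours * 720)
        import pandas as pd

        df = pd.DataFrame(
            {
                "t5": np.arange(n) * 5.0,
                "odba5": 0.1,
                "tbody5": 30.0,
                "light5": 10.0,
                "tamb5": 15.0,
                "sun_elev": 0.0,
                "n_valid": 125,
            }
        )
        return accel.SensorTrace("c", df, START)

    def test_73h_becomes_72h(self):
        tr = accel.trim_edges(self._trace(73), 1800.0)
        assert len(tr) * 5.0 == pytest.approx(72 * 3600.0)

    def test_first_bin_after_trim(self):
        tr = accel.trim_edges(self._trace(24), 1800.0)
        assert tr.t5[0] == 1800.0

    def test_too_short_trace_empties_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            tr = accel.trim_edges(self._trace(59 / 60), 1800.0)
        assert len(tr) == 0
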