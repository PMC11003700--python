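import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakreg.formats_io import CoverageTrack
from peakreg.signal_matrix import (
    MetageneProfile,
    SignalMatrix,
    compute_matrix,
    metagene,
    peak_anchor,
    peak_center_score,
    rpkm_value,
    summit_change,
)

from .conftest import make_peak, random_track
from .oracles import naive_center_score, naive_matrix


class TestPeakAnchor:
    @pytest.mark.parametrize(
        "start,end,summit,expected",
        [(100, 200, 40, 140), (100, 200, None, 150), (0, 1, None, 0)],
    )
    def test_summit_preferred_else_midpoint(self, start, end, summit, expected):
        assert peak_anchor(make_peak("chr1", start, end, summit=summit)) == expected


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [(50, 100, 1e7, 50.0), (0, 100, 1e7, 0.0), (7, 250, 2e6, 14.0)],
    )
    def test_values(self, count, length, total, expected):
        assert rpkm_value(count, length, total) == pytest.approx(expected)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            rpkm_value(1, 0, 1e6)
        with pytest.raises(ValueError):
            rpkm_value(1, 100, 0)

    @given(count=st.floats(0, 1e6), factor=st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_count_inverse_in_library(self, count, factor):
        base = rpkm_value(count, 500, 1e6)
        assert rpkm_value(count * factor, 500, 1e6) == pytest.approx(base * factor)
        assert rpkm_value(count, 500, 1e6 * factor) == pytest.approx(base / factor)


class TestComputeMatrix:
    def test_constant_track(self):
        track = CoverageTrack({"chr1": [(0, 20000, 2.0)]}, 1e6)
        m = compute_matrix(track, [make_peak("chr1", 9000, 11000)], 3000, 10)
        assert m.values.shape == (1, 600)
        np.testing.assert_allclose(m.values, 2.0)

    def test_single_base_spike_lands_in_covering_bin(self):
        # one base of value 5.0 exactly at the anchor: covering bin = 5/10
        track = CoverageTrack({"chr1": [(10000, 10001, 5.0)]}, 1e6)
        m = compute_matrix(track, [make_peak("chr1", 9000, 11000)], 3000, 10)
        expected = np.zeros(600)
        expected[300] = 0.5
        np.testing.assert_allclose(m.values[0], expected)

    def test_zero_peaks_gives_zero_rows(self):
        track = CoverageTrack({"chr1": [(0, 10, 1.0)]}, 1e6)
        assert compute_matrix(track, [], 3000, 10).values.shape == (0, 600)

    def test_unknown_chromosome_row_is_zero(self, caplog):
        track = CoverageTrack({"chr1": [(0, 10, 1.0)]}, 1e6)
        m = compute_matrix(track, [make_peak("chrX", 5000, 5100)], 3000, 10)
        np.testing.assert_array_equal(m.values, 0.0)

    def test_flank_not_divisible_by_bin_raises(self):
        track = CoverageTrack({"chr1": [(0, 10, 1.0)]}, 1e6)
        with pytest.raises(ValueError):
            compute_matrix(track, [], 3005, 10)

    def test_matches_per_base_oracle_on_random_tracks(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            track, steps = random_track(rng)
            peaks = [
                make_peak("chr1", int(s), int(s) + 20,
                          summit=int(rng.integers(0, 20)))
                for s in rng.integers(0, 380, size=3)
            ]
            flank, bin_size = 40, 10
            m = compute_matrix(track, peaks, flank, bin_size)
            anchors = [("chr1", peak_anchor(p)) for p in peaks]
            expected = naive_matrix(steps, anchors, flank, bin_size)
            np.testing.assert_allclose(m.values, expected, atol=1e-9)

    def test_total_signal_conservation(self):
        rng = np.random.default_rng(5)
        track, steps = random_track(rng)
        peaks = [make_peak("chr1", 100, 140), make_peak("chr1", 250, 260)]
        m = compute_matrix(track, peaks, 40, 10)
        anchors = [("chr1", peak_anchor(p)) for p in peaks]
        oracle = naive_matrix(steps, anchors, 40, 10)
        assert m.values.sum() == pytest.approx(oracle.sum(), abs=1e-9)


class TestCenterScore:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        return SignalMatrix(tuple(f"p{i}" for i in range(values.shape[0])),
                            values, 10, values.shape[1] * 10 // 2)

    def test_uniform_bins(self):
        m = self._matrix(np.full((2, 600), 2.0))
        np.testing.assert_allclose(peak_center_score(m, 500), [200.0, 200.0])

    def test_alternating_bins(self):
        row = np.tile([1.0, 0.0], 300)
        np.testing.assert_allclose(peak_center_score(self._matrix([row]), 500), [50.0])

    def test_window_validation(self):
        m = self._matrix(np.zeros((1, 600)))
        with pytest.raises(ValueError):
            peak_center_score(m, 505)
        with pytest.raises(ValueError):
            peak_center_score(m, 4000)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 4, size=(20, 600))
        m = self._matrix(values)
        np.testing.assert_allclose(
            peak_center_score(m, 500), naive_center_score(values, 10, 3000, 500)
        )


class TestMetagene:
    def test_column_means(self):
        m = SignalMatrix(("a", "b"), np.array([[1.0, 3.0], [3.0, 5.0]]), 10, 10)
        prof = metagene(m)
        np.testing.assert_allclose(prof.mean_signal, [2.0, 4.0])
        assert prof.n_peaks == 2

    def test_empty_matrix_raises(self):
        m = SignalMatrix((), np.zeros((0, 2)), 10, 10)
        with pytest.raises(ValueError):
            metagene(m)

    def test_matches_brute_force_column_mean(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 10, size=(1000, 60))
        m = SignalMatrix(tuple(map(str, range(1000))), values, 10, 300)
        np.testing.assert_allclose(metagene(m).mean_signal, values.mean(axis=0))


class TestSummitChange:
    def _profile(self, values):
        values = np.asarray(values, dtype=float)
        return MetageneProfile(np.arange(len(values)), values, 10)

    @pytest.mark.parametrize(
        "ctrl,kd,expected", [(10, 5, 50.0), (10, 10, 0.0), (20, 19, 5.0)]
    )
    def test_percent_decrease(self, ctrl, kd, expected):
        p_ctrl = self._profile([0, ctrl, ctrl, 0])
        p_kd = self._profile([0, kd, kd, 0])
        assert summit_change(p_ctrl, p_kd) == pytest.approx(expected)

    def test_zero_control_summit_raises(self):
        flat = self._profile([0, 0, 0, 0])
        with pytest.raises(ValueError):
            summit_change(flat, flat)
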