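"""Peak tests, attentional gain, lateralization, correlation, behavioral t-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import freqtag as ft
from freqtag.errors import (
    DegenerateInputError,
    InvalidParameterError,
    MontageError,
    OffGridError,
    PairedDataError,
)


class TestNeighborBins:
    def test_two_per_side_at_one_hz(self):
        nbs = ft.neighbor_bins(1.0, 0.1, 2)
        assert nbs == pytest.approx([0.8, 0.9, 1.1, 1.2])

    def test_one_per_side(self):
        assert ft.neighbor_bins(2.0, 0.1, 1) == pytest.approx([1.9, 2.1])

    def test_excludes_center(self):
        assert not any(abs(nb - 1.0) < 1e-9 for nb in ft.neighbor_bins(1.0, 0.1, 2))

    def test_neighbors_outside_grid_rejected(self):
        grid = np.arange(0.5, 4.6, 0.1)
        with pytest.raises(OffGridError):
            ft.neighbor_bins(0.6, 0.1, 2, grid=grid)


class TestPeakTest:
    def test_hand_computed_paired_t(self):
        # diffs {0.3, 0.1, 0.4, 0.2, 0.0}: mean 0.2, sd 0.1581,
        # t = 0.2 / (0.1581 / sqrt(5)) = 2.8284, one-tailed p(df=4) = 0.0237
        values = np.array([0.3, 0.1, 0.4, 0.2, 0.0])
        res = ft.peak_test(values, np.zeros(5), m_tests=1)
        assert res.t == pytest.approx(2.8284, abs=1e-4)
        assert res.p_raw == pytest.approx(0.0237, abs=5e-4)
        assert res.df == 4

    def test_all_zero_differences(self):
        res = ft.peak_test([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0])
        assert res.t == 0.0
        assert res.p_raw == 0.5
        assert res.degenerate

    def test_constant_positive_differences(self):
        res = ft.peak_test([2.0, 2.0, 2.0, 2.0], [1.0, 1.0, 1.0, 1.0])
        assert res.t == math.inf
        assert res.p_raw == 0.0
        assert res.p_corrected == 0.0
        assert res.degenerate

    def test_bonferroni_correction(self):
        values = np.array([0.3, 0.1, 0.4, 0.2, 0.0])
        raw = ft.peak_test(values, np.zeros(5), m_tests=1)
        corr = ft.peak_test(values, np.zeros(5), m_tests=4)
        assert corr.p_corrected == pytest.approx(min(1.0, 4 * raw.p_raw))

    def test_matches_scipy_reference(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        x = rng.normal(1.2, 0.5, 20)
        y = rng.normal(1.0, 0.5, 20)
        res = ft.peak_test(x, y, m_tests=1)
        ref = sps.ttest_rel(x, y, alternative="greater")
        assert res.t == pytest.approx(float(ref.statistic), rel=1e-12)
        assert res.p_raw == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(PairedDataError):
            ft.peak_test([1.0, 2.0, 3.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000), st.integers(1, 10))
    def test_bonferroni_dominance(self, seed, m):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0, 1, 8)
        res = ft.peak_test(x, y, m_tests=m)
        assert res.p_corrected >= res.p_raw
        assert res.p_corrected <= 1.0
        if m * res.p_raw > 1.0:
            assert res.p_corrected == 1.0


class TestAttentionalGain:
    def test_equal_conditions_give_zero(self):
        assert ft.attentional_gain(0.4, 0.4) == 0.0

    def test_direct_formula(self):
        assert ft.attentional_gain(0.6, 0.2) == pytest.approx(0.5)

    def test_boundary_when_passive_vanishes(self):
        assert ft.attentional_gain(0.7, 0.0) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DegenerateInputError):
            ft.attentional_gain(0.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_antisymmetric_and_bounded(self, a, p):
        g = ft.attentional_gain(a, p)
        assert g == pytest.approx(-ft.attentional_gain(p, a), rel=1e-12)
        assert -1.0 <= g <= 1.0

    def test_group_summary(self):
        res = ft.attentional_gains([0.6, 0.5, 0.4], [0.2, 0.5, 0.6], freq=2.0)
        assert res.gains == pytest.approx([0.5, 0.0, -0.2])
        assert res.mean == pytest.approx(0.1)


def _zspec(values, freqs, labels):
    return ft.ITPCzSpectrum(values=values, freqs=freqs, n_trials=48,
                            channel_labels=labels,
                            channel_mean=values.mean(axis=0))


class TestLateralization:
    freqs = np.arange(0.5, 4.55, 0.1)

    def _spec(self, left_peak, right_peak):
        idx = int(np.argmin(np.abs(self.freqs - 2.0)))
        values = np.ones((2, len(self.freqs)))
        values[0, idx] += left_peak
        values[1, idx] += right_peak
        return _zspec(values, self.freqs, ("C3", "C4"))

    def test_symmetric_data_gives_zero(self):
        spec = self._spec(3.0, 3.0)
        assert ft.lateralization_effect(spec, 2.0, ["C3"], ["C4"]) == pytest.approx(0.0)

    def test_right_dominance_is_positive(self):
        spec = self._spec(1.5, 3.0)
        assert ft.lateralization_effect(spec, 2.0, ["C3"], ["C4"]) > 0

    def test_unknown_channel_rejected(self):
        spec = self._spec(1.0, 1.0)
        with pytest.raises(MontageError):
            ft.lateralization_effect(spec, 2.0, ["C5"], ["C4"])

    def test_overlapping_channel_sets_rejected(self):
        spec = self._spec(1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            ft.lateralization_effect(spec, 2.0, ["C3"], ["C3"])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = ft.pearson_corr(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_null_calibration_of_mean_r(self):
        rng = np.random.default_rng(6)
        rs = []
        for _ in range(1000):
            x = rng.standard_normal(24)
            y = rng.standard_normal(24)
            rs.append(ft.pearson_corr(x, y).r)
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            ft.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBehavioral:
    def test_identical_groups_give_zero_t(self):
        res = ft.behavioral_tests([4.0, 5.0, 4.5], [4.0, 5.0, 4.5], midpoint=3.0)
        assert res["between"]["t"] == pytest.approx(0.0)

    def test_group_constant_at_midpoint_gives_zero_t(self):
        res = ft.behavioral_tests([3.0, 3.0, 3.0], [4.0, 5.0, 4.0], midpoint=3.0)
        assert res["group1_vs_midpoint"]["t"] == 0.0

    def test_hand_computed_independent_t(self):
        # {5,5,4,5} vs {4,4,3,4}: means 4.75/3.75, pooled sd 0.5,
        # se = 0.5 * sqrt(1/4 + 1/4) -> t = 1.0 / 0.35355 = 2.8284
        res = ft.behavioral_tests([5, 5, 4, 5], [4, 4, 3, 4], midpoint=3.0)
        assert res["between"]["t"] == pytest.approx(2.8284, abs=1e-4)
        assert res["between"]["df"] == 6

    def test_welch_flag_changes_df(self):
        pooled = ft.behavioral_tests([5, 5, 4, 5], [4, 4, 3, 3, 2, 4], midpoint=3.0)
        welch = ft.behavioral_tests([5, 5, 4, 5], [4, 4, 3, 3, 2, 4], midpoint=3.0,
                                    equal_var=False)
        assert pooled["between"]["df"] == 8
        assert welch["between"]["df"] != pooled["between"]["df"]
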