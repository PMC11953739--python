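import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from quadassay.assay_data import ExperimentSet, QuadrantCounts
from quadassay.errors import InfiniteEffectError, InsufficientDataError, UndefinedInputError
from quadassay.metrics import (
    compute_chemotaxis_index,
    compute_dispersal,
    compute_effect_size,
    compute_metrics,
    compute_response_ratio,
    orientation_consistency,
    summarize_group,
    unpaired_t_test,
)
from tests.conftest import make_record

# frozen oracle: exact symbolic evaluation of -sum(p*log2(p)) for (1,45,45,9)
DISPERSAL_1_45_45_9 = 1.4158951529482093

counts_strategy = st.tuples(*[st.integers(0, 400)] * 4).filter(lambda c: sum(c) > 0)


class TestDispersal:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((25, 25, 25, 25), 2.0),
            ((0, 50, 50, 0), 1.0),
            ((100, 0, 0, 0), 0.0),
        ],
    )
    def test_exact_regimes(self, counts, expected):
        assert compute_dispersal(QuadrantCounts(*counts)) == expected

    def test_derived_value(self):
        got = compute_dispersal(QuadrantCounts(1, 45, 45, 9))
        assert got == pytest.approx(DISPERSAL_1_45_45_9, abs=1e-12)

    def test_empty_arena_raises(self):
        with pytest.raises(UndefinedInputError):
            compute_dispersal(QuadrantCounts(0, 0, 0, 0))

    @given(counts=counts_strategy)
    def test_bounds_and_oracle(self, counts):
        qc = QuadrantCounts(*counts)
        h = compute_dispersal(qc)
        assert 0.0 <= h <= 2.0 + 1e-12
        # independent route: scipy's entropy on the raw counts
        assert h == pytest.approx(float(stats.entropy(list(counts), base=2)), abs=1e-9)

    def test_exhaustive_small_compositions_against_oracle(self):
        total = 12
        for q1 in range(total + 1):
            for q2 in range(total - q1 + 1):
                for q3 in range(total - q1 - q2 + 1):
                    q4 = total - q1 - q2 - q3
                    counts = (q1, q2, q3, q4)
                    h = compute_dispersal(QuadrantCounts(*counts))
                    assert h == pytest.approx(
                        float(stats.entropy(list(counts), base=2)), abs=1e-9
                    )
                    occupied = sum(c > 0 for c in counts)
                    if occupied == 1:
                        assert h == 0.0
                    if counts == (3, 3, 3, 3):
                        assert h == 2.0

    @given(counts=counts_strategy)
    def test_reversal_invariance(self, counts):
        fwd = compute_dispersal(QuadrantCounts(*counts))
        rev = compute_dispersal(QuadrantCounts(*counts[::-1]))
        assert fwd == pytest.approx(rev, abs=1e-12)


class TestResponseRatio:
    @pytest.mark.parametrize(
        "counts, expected",
        [((1, 45, 45, 9), 0.1), ((5, 15, 35, 45), 0.5), ((25, 25, 25, 25), 0.5)],
    )
    def test_values(self, counts, expected):
        assert compute_response_ratio(QuadrantCounts(*counts)) == pytest.approx(expected)

    def test_empty_arena_raises(self):
        with pytest.raises(UndefinedInputError):
            compute_response_ratio(QuadrantCounts(0, 0, 0, 0))

    @given(counts=counts_strategy, k=st.integers(1, 9))
    def test_scale_and_reversal_invariance(self, counts, k):
        base = compute_response_ratio(QuadrantCounts(*counts))
        scaled = compute_response_ratio(QuadrantCounts(*[k * c for c in counts]))
        reversed_ = compute_response_ratio(QuadrantCounts(*counts[::-1]))
        assert 0.0 <= base <= 1.0
        assert scaled == pytest.approx(base, abs=1e-12)
        assert reversed_ == pytest.approx(base, abs=1e-12)


class TestChemotaxisIndex:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((1, 45, 45, 9), 0.8),
            ((5, 15, 35, 45), 0.8),
            ((10, 40, 40, 10), 0.0),
        ],
    )
    def test_values(self, counts, expected):
        assert compute_chemotaxis_index(QuadrantCounts(*counts)) == pytest.approx(expected)

    def test_undefined_when_extremes_empty(self):
        assert compute_chemotaxis_index(QuadrantCounts(0, 50, 50, 0)) is None

    @given(counts=counts_strategy)
    def test_antisymmetry_under_extreme_swap(self, counts):
        q1, q2, q3, q4 = counts
        fwd = compute_chemotaxis_index(QuadrantCounts(q1, q2, q3, q4))
        swapped = compute_chemotaxis_index(QuadrantCounts(q4, q2, q3, q1))
        if fwd is None:
            assert swapped is None
        else:
            assert -1.0 <= fwd <= 1.0
            assert swapped == pytest.approx(-fwd, abs=1e-12)

    @given(counts=counts_strategy.filter(lambda c: c[0] + c[3] > 0), k=st.integers(1, 9))
    def test_scale_invariance(self, counts, k):
        base = compute_chemotaxis_index(QuadrantCounts(*counts))
        scaled = compute_chemotaxis_index(QuadrantCounts(*[k * c for c in counts]))
        assert scaled == pytest.approx(base, abs=1e-12)


class TestEffectSize:
    def _groups(self, mean_test, mean_control, sd):
        # three-point groups with exact sample mean and sd
        return (
            [mean_test - sd, mean_test, mean_test + sd],
            [mean_control - sd, mean_control, mean_control + sd],
        )

    def test_worked_example_sd_point_one(self):
        test, control = self._groups(0.8, 0.0, 0.1)
        assert compute_effect_size(test, control).cohens_d == pytest.approx(8.0)

    def test_worked_example_sd_point_five(self):
        test, control = self._groups(0.8, 0.0, 0.5)
        assert compute_effect_size(test, control).cohens_d == pytest.approx(1.6)

    def test_identical_groups_zero(self):
        assert compute_effect_size([0.5, 0.7], [0.5, 0.7]).cohens_d == 0.0

    def test_constant_groups_differing_means_error(self):
        with pytest.raises(InfiniteEffectError):
            compute_effect_size([0.5, 0.5], [0.4, 0.4])

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compute_effect_size([0.5], [0.4, 0.6])

    def test_equal_weight_variance_averaging_ignores_group_sizes(self):
        # unbalanced groups: denominator must stay sqrt((v1+v2)/2), not pooled by df
        test = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        control = [0.0, 1.0]
        sd_t = float(np.std(test, ddof=1))
        sd_c = float(np.std(control, ddof=1))
        expected = (np.mean(test) - np.mean(control)) / math.sqrt((sd_t**2 + sd_c**2) / 2)
        assert compute_effect_size(test, control).cohens_d == pytest.approx(expected)

    # dyadic grid keeps shift/scale arithmetic exact in binary floating point
    _grid = st.integers(-160, 160).map(lambda i: i / 32.0)

    @given(
        test=st.lists(_grid, min_size=2, max_size=8),
        control=st.lists(_grid, min_size=2, max_size=8),
        shift=st.integers(-320, 320).map(lambda i: i / 32.0),
        scale=st.sampled_from([0.25, 0.5, 2.0, 4.0, 8.0]),
    )
    def test_shift_and_scale_invariance(self, test, control, shift, scale):
        try:
            base = compute_effect_size(test, control).cohens_d
        except InfiniteEffectError:
            return
        shifted = compute_effect_size(
            [v + shift for v in test], [v + shift for v in control]
        ).cohens_d
        scaled = compute_effect_size(
            [v * scale for v in test], [v * scale for v in control]
        ).cohens_d
        assert shifted == pytest.approx(base, abs=1e-6, rel=1e-6)
        assert scaled == pytest.approx(base, abs=1e-6, rel=1e-6)

    def test_sign_matches_mean_difference(self):
        assert compute_effect_size([1.0, 1.2], [0.0, 0.1]).cohens_d > 0
        assert compute_effect_size([0.0, 0.1], [1.0, 1.2]).cohens_d < 0


class TestUnpairedTTest:
    def test_identical_groups(self):
        report = unpaired_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert report.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert report.p_value == pytest.approx(1.0)

    def test_identical_constant_groups(self):
        report = unpaired_t_test([0.5, 0.5], [0.5, 0.5])
        assert report.t_statistic == 0.0
        assert report.p_value == 1.0

    def test_derived_pooled_t(self):
        # frozen oracle: hand-computed pooled-variance t for these groups
        report = unpaired_t_test([0.8, 0.9, 0.85], [0.0, 0.05, -0.05])
        assert report.t_statistic == pytest.approx(20.82066281365702, rel=1e-12)
        assert report.degrees_of_freedom == 4
        assert report.p_value == pytest.approx(3.1442966633282314e-05, rel=1e-9)

    def test_swap_negates_t_keeps_p(self):
        a, b = [0.8, 0.9, 0.85], [0.0, 0.05, -0.05]
        fwd = unpaired_t_test(a, b)
        rev = unpaired_t_test(b, a)
        assert rev.t_statistic == pytest.approx(-fwd.t_statistic)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_welch_variant_differs_under_unequal_variance(self):
        a = [0.0, 0.1, 0.05, 0.02]
        b = [1.0, 3.0, -2.0, 4.0, -1.0]
        student = unpaired_t_test(a, b)
        welch = unpaired_t_test(a, b, welch=True)
        assert student.degrees_of_freedom == 7
        assert welch.degrees_of_freedom != student.degrees_of_freedom

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            unpaired_t_test([0.5], [0.4, 0.6])


class TestSummarizeGroup:
    def test_median_middle_order_statistic(self):
        assert summarize_group([0.8, 0.83, 0.9]).median == pytest.approx(0.83)

    def test_constant_sequence(self):
        summary = summarize_group([0.5, 0.5, 0.5])
        assert summary.sd == 0.0
        assert summary.ci95_low == summary.ci95_high == 0.5

    def test_derived_ci(self):
        # frozen oracle: 3 +/- t(0.975, df=4) * sd / sqrt(5)
        summary = summarize_group([1, 2, 3, 4, 5])
        assert summary.mean == 3.0
        assert summary.sd == pytest.approx(1.5811388300841898)
        assert summary.ci95_low == pytest.approx(1.0367568385224393, rel=1e-9)
        assert summary.ci95_high == pytest.approx(4.9632431614775605, rel=1e-9)

    def test_single_value(self):
        summary = summarize_group([0.7])
        assert summary.mean == 0.7
        assert summary.sd is None and summary.ci95_low is None

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            summarize_group([])

    def test_mean_within_ci(self):
        summary = summarize_group([0.2, 0.9, 0.4, 0.6])
        assert summary.ci95_low <= summary.mean <= summary.ci95_high


class TestOrientationConsistency:
    def _experiment(self, counts_a, counts_b):
        arenas = []
        for i, c in enumerate(counts_a, start=1):
            arenas.append(make_record(plate_id=f"A{i}", orientation="A", counts=c))
        for i, c in enumerate(counts_b, start=1):
            arenas.append(make_record(plate_id=f"B{i}", orientation="B", counts=c))
        return ExperimentSet(odorant="butanone 10%", arenas=arenas)

    def test_identical_counts_zero_difference(self):
        counts = [(5, 15, 35, 45)] * 3
        # orientation B counts mirrored so canonical indices are identical
        exp = self._experiment(counts, [c[::-1] for c in counts])
        comparison = orientation_consistency(exp)
        assert comparison.difference == 0.0
        assert comparison.p_value == 1.0
        assert not comparison.flagged

    def test_gross_disagreement_flagged(self):
        a = [(2, 15, 35, 95), (3, 14, 36, 96), (1, 16, 34, 94)]
        b_physical = [(90, 30, 16, 95), (88, 31, 15, 94), (91, 29, 17, 96)]
        exp = self._experiment(a, b_physical)
        comparison = orientation_consistency(exp)
        assert comparison.flagged
        assert comparison.p_value < 0.05

    def test_missing_orientation_raises(self):
        exp = self._experiment([(5, 15, 35, 45)] * 3, [])
        with pytest.raises(InsufficientDataError):
            orientation_consistency(exp)


def test_compute_metrics_canonicalizes_records():
    rec = make_record(orientation="B", counts=(45, 35, 15, 5))
    m = compute_metrics(rec)
    assert m.chemotaxis_index == pytest.approx(0.8)
    assert m.response_ratio == pytest.approx(0.5)
    assert m.n_total == 100
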