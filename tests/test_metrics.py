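import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from uropanel.cohort import MarkerDefinition, MarkerLevel
from uropanel.errors import UndefinedMetricError, UropanelError
from uropanel.metrics import (
    ClassificationStatus,
    classify_marker,
    normalize_to_creatinine,
    percentile_threshold,
    performance,
    roc_curve,
    threshold_at_min_specificity,
    wilcoxon_rank_sum,
)

CXCL16 = MarkerDefinition("CXCL16", MarkerLevel.PROTEIN, 648.52)
ALOX5 = MarkerDefinition("ALOX5", MarkerLevel.METHYLATION, 0.435)

POS = ClassificationStatus.POSITIVE
NEG = ClassificationStatus.NEGATIVE
UNC = ClassificationStatus.UNCLASSIFIED


class TestNormalize:
    @pytest.mark.parametrize(
        "conc,creat,expected", [(1000.0, 2.0, 500.0), (0.0, 1.5, 0.0), (372.9, 1.0, 372.9)]
    )
    def test_quotient(self, conc, creat, expected):
        assert normalize_to_creatinine(conc, creat) == pytest.approx(expected)

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(UropanelError, match="creatinine"):
            normalize_to_creatinine(100.0, 0.0)


class TestClassify:
    def test_boundary_value_is_positive(self):
        # positivity is value >= threshold, boundary inclusive
        assert classify_marker(648.52, CXCL16) is POS

    def test_below_threshold_negative(self):
        assert classify_marker(0.434, ALOX5) is NEG

    @pytest.mark.parametrize("value", [None, float("nan")])
    def test_absent_value_unclassified(self, value):
        assert classify_marker(value, CXCL16) is UNC


class TestPerformance:
    def test_perfect_classification(self):
        perf = performance([POS] * 3 + [NEG] * 3, [True] * 3 + [False] * 3)
        assert (perf.sensitivity, perf.specificity) == (1.0, 1.0)

    def test_half_sensitive(self):
        perf = performance([POS, POS, NEG, NEG, NEG], [True] * 4 + [False])
        assert perf.sensitivity == 0.5
        assert perf.n_cases_used == 4

    def test_unclassified_excluded_from_denominator(self):
        statuses = [POS, NEG, NEG, NEG, NEG, UNC]
        labels = [True, False, False, False, False, False]
        perf = performance(statuses, labels)
        assert perf.specificity == 1.0
        assert perf.n_controls_used == 4

    def test_no_classified_cases_raises(self):
        with pytest.raises(UndefinedMetricError):
            performance([UNC, NEG], [True, False])

    def test_order_invariance(self):
        statuses = [POS, NEG, UNC, POS, NEG]
        labels = [True, False, True, False, True]
        ref = performance(statuses, labels)
        for perm in itertools.permutations(range(5)):
            p = performance([statuses[i] for i in perm], [labels[i] for i in perm])
            assert (p.sensitivity, p.specificity) == (ref.sensitivity, ref.specificity)
            break  # spot-check plus the reversed order below
        rev = performance(statuses[::-1], labels[::-1])
        assert (rev.sensitivity, rev.specificity) == (ref.sensitivity, ref.specificity)


class TestPercentileThreshold:
    def test_nearest_rank_on_1_to_100(self):
        assert percentile_threshold(list(range(1, 101)), 0.95) == 95

    def test_q_one_gives_maximum(self):
        assert percentile_threshold([3.0, 9.0, 1.0], 1.0) == 9.0

    def test_single_control(self):
        assert percentile_threshold([7.0], 0.37) == 7.0

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50),
        st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_specificity_guarantee_on_defining_sample(self, controls, q):
        """At the nearest-rank threshold, at least a q-fraction of the
        defining controls sit at or below it; without ties at the threshold
        this makes specificity >= q - 1/n under >=-positivity."""
        n = len(controls)
        t = percentile_threshold(controls, q)
        assert sum(1 for v in controls if v <= t) / n >= q - 1e-12
        if sum(1 for v in controls if v == t) == 1:
            spec = sum(1 for v in controls if v < t) / n
            assert spec >= q - 1.0 / n - 1e-12


class TestRocCurve:
    def test_perfectly_separated(self):
        curve = roc_curve([10, 11, 1, 2], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)

    def test_complete_ties(self):
        curve = roc_curve([5.0] * 5, [True, True, False, False, False])
        assert curve.auc == pytest.approx(0.5)

    def test_interleaved_075(self):
        # 3 winning case-control pairs out of 4
        curve = roc_curve([3, 1, 2, 0], [True, True, False, False])
        assert curve.auc == pytest.approx(0.75)

    def test_missing_values_excluded(self):
        with_missing = roc_curve([3, 1, None, 2, 0], [True, True, True, False, False])
        without = roc_curve([3, 1, 2, 0], [True, True, False, False])
        assert with_missing.auc == without.auc
        assert with_missing.n_cases == 2

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_curve([1.0, 2.0], [True, True])

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=30),
        st.integers(0, 2**30),
    )
    @settings(deadline=None, max_examples=150)
    def test_monotone_and_anchored(self, values, seed):
        rng = np.random.default_rng(seed)
        labels = rng.random(len(values)) < 0.5
        if labels.all() or not labels.any():
            labels[0] = True
            labels[-1] = False
            if len(values) == 2 and labels.all():
                return
        curve = roc_curve([float(v) for v in values], labels)
        sens, spec = curve.sensitivities, curve.specificities
        assert np.all(np.diff(sens) >= 0)
        assert np.all(np.diff(spec) <= 0)
        assert (sens[0], spec[0]) == (0.0, 1.0)
        assert (sens[-1], spec[-1]) == (1.0, 0.0)

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=6),
        st.lists(st.integers(0, 6), min_size=1, max_size=6),
    )
    @settings(deadline=None, max_examples=200)
    def test_auc_equals_mann_whitney_probability(self, cases, controls):
        """Trapezoid AUC == (#case>control + 0.5 #ties) / (n_case*n_control)."""
        values = [float(v) for v in cases + controls]
        labels = [True] * len(cases) + [False] * len(controls)
        curve = roc_curve(values, labels)
        wins = sum(1 for c in cases for k in controls if c > k)
        ties = sum(1 for c in cases for k in controls if c == k)
        expected = (wins + 0.5 * ties) / (len(cases) * len(controls))
        assert curve.auc == pytest.approx(expected, abs=1e-12)


class TestThresholdAtMinSpecificity:
    def test_perfect_marker(self):
        curve = roc_curve([10, 11, 1, 2], [True, True, False, False])
        t, perf = threshold_at_min_specificity(curve, 0.95)
        assert perf.sensitivity == 1.0
        assert perf.specificity == 1.0

    def test_single_case_above_controls(self):
        curve = roc_curve([5, 1, 2, 3, 4], [True, False, False, False, False])
        t, perf = threshold_at_min_specificity(curve, 0.95)
        assert t == 5.0
        assert (perf.sensitivity, perf.specificity) == (1.0, 1.0)

    def test_min_spec_one_with_overlap(self):
        # overlapping distributions: threshold must sit above every control
        curve = roc_curve([2, 4, 1, 3], [True, True, False, False])
        t, perf = threshold_at_min_specificity(curve, 1.0)
        assert perf.specificity == 1.0
        assert t > 3

    def test_tie_broken_toward_higher_specificity(self):
        # sens 1.0 attainable at thresholds 2 (spec 0.5) and 2? construct:
        curve = roc_curve([5, 6, 1, 4], [True, True, False, False])
        t, perf = threshold_at_min_specificity(curve, 0.5)
        assert perf.sensitivity == 1.0
        assert perf.specificity == 1.0  # not the lower-spec tie


class TestWilcoxon:
    def test_identical_multisets_give_p_near_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_exact_p_for_fully_separated_triples(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2/20 of the C(6,3) assignments

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8).tolist()
        y = rng.normal(1.0, size=6).tolist()
        _, pxy = wilcoxon_rank_sum(x, y)
        _, pyx = wilcoxon_rank_sum(y, x)
        assert pxy == pytest.approx(pyx, abs=1e-12)

    def test_all_identical_values_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 9)))
            y = rng.normal(0.7, size=int(rng.integers(3, 9)))
            _, p = wilcoxon_rank_sum(x, y, method="exact")
            p_ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(UropanelError):
            wilcoxon_rank_sum([], [1.0])
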