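import numpy as np
import pytest

from uropanel.cohort import MarkerDefinition, MarkerLevel, case_control_labels
from uropanel.errors import ConfigurationError, UropanelError
from uropanel.metrics import ClassificationStatus
from uropanel.panel import (
    OptimizerConfig,
    Panel,
    candidate_thresholds,
    cross_validate,
    optimize_panel,
    score_subject,
)
from uropanel.synthetic import generate_separable_cohort

from conftest import make_cohort, random_integer_cohort
from oracles import brute_force_optimize


class TestCandidateThresholds:
    def test_single_class_change_gap(self):
        assert candidate_thresholds([1, 2, 3, 4], [False, False, True, True]) == [2.5]

    def test_all_identical_no_candidates(self):
        assert candidate_thresholds([2, 2, 2], [True, False, True]) == []

    def test_fully_interleaved_every_gap(self):
        got = candidate_thresholds([1, 3, 2, 4], [True, True, False, False])
        assert got == [1.5, 2.5, 3.5]

    def test_single_class_warns_empty(self):
        with pytest.warns(UserWarning):
            assert candidate_thresholds([1, 2], [True, True]) == []

    def test_tied_mixed_value_merges_composition(self):
        # value 2 holds both classes; the 1|2 gap separates {ctrl} from {both}
        got = candidate_thresholds([1, 2, 2, 3], [False, True, False, True])
        assert got == [1.5, 2.5]


class TestScoreSubject:
    PANEL = Panel(markers=("A", "B", "C"), thresholds=(1.0, 2.0, 3.0), score_threshold=2)

    def test_meets_two_of_three(self):
        score, status = score_subject({"A": 1.5, "B": 5.0, "C": 0.1}, self.PANEL)
        assert score == 2
        assert status is ClassificationStatus.POSITIVE

    def test_one_of_three_negative(self):
        score, status = score_subject({"A": 1.5, "B": 0.0, "C": 0.1}, self.PANEL)
        assert (score, status) == (1, ClassificationStatus.NEGATIVE)

    def test_any_missing_panel_marker_unclassified(self):
        _, status = score_subject({"A": 9.0, "B": 9.0, "C": None}, self.PANEL)
        assert status is ClassificationStatus.UNCLASSIFIED

    def test_boundary_counts_toward_score(self):
        score, status = score_subject({"A": 1.0, "B": 2.0, "C": 0.0}, self.PANEL)
        assert score == 2
        assert status is ClassificationStatus.POSITIVE


def _perfect_cohort():
    markers = [
        MarkerDefinition("GOOD", MarkerLevel.PROTEIN, 1.0),
        MarkerDefinition("NOISE", MarkerLevel.PROTEIN, 1.0),
    ]
    rows = []
    rng = np.random.default_rng(0)
    for i in range(20):
        is_case = i < 10
        rows.append(
            (
                "uca" if is_case else "no_cancer",
                {"GOOD": 10.0 + i if is_case else float(i - 10), "NOISE": float(rng.uniform(0, 1))},
                {"grade": "unknown"} if is_case else {},
            )
        )
    return make_cohort(markers, rows)


class TestOptimizePanel:
    def test_perfectly_separating_marker_chosen_alone(self):
        panel = optimize_panel(_perfect_cohort())
        assert panel.markers == ("GOOD",)
        assert panel.score_threshold == 1
        perf = panel.training_performance
        assert (perf.sensitivity, perf.specificity) == (1.0, 1.0)
        assert panel.feasible

    def test_matches_brute_force_on_random_instances(self):
        """Vectorised search == naive triple-loop enumerator (spot sample;
        the full 200-instance comparison runs in the acceptance suite)."""
        rng = np.random.default_rng(100)
        cfg = OptimizerConfig(max_candidates_per_marker=None)
        for _ in range(25):
            table, names = random_integer_cohort(
                rng, n_markers=int(rng.integers(1, 4)), n_subjects=int(rng.integers(8, 41))
            )
            rows = [dict(s.values) for s in table.subjects]
            labels = case_control_labels(table).tolist()
            oracle = brute_force_optimize(
                rows, labels, names, cfg.min_specificity, cfg.max_panel_size
            )
            if oracle is None:
                with pytest.raises(UropanelError):
                    optimize_panel(table, names, cfg)
                continue
            o_markers, o_thr, o_s, o_sens, o_spec, o_feas = oracle
            panel = optimize_panel(table, names, cfg)
            assert panel.markers == o_markers
            assert panel.thresholds == pytest.approx(o_thr)
            assert panel.score_threshold == o_s
            assert panel.feasible == o_feas
            assert panel.training_performance.sensitivity == pytest.approx(o_sens)
            assert panel.training_performance.specificity == pytest.approx(o_spec)

    def test_constraint_respected_when_feasible(self):
        rng = np.random.default_rng(200)
        for _ in range(20):
            table, names = random_integer_cohort(rng, n_markers=2, n_subjects=30)
            panel = optimize_panel(table, names)
            if panel.feasible:
                assert panel.training_performance.specificity >= 0.95

    def test_raising_min_specificity_never_raises_sensitivity(self):
        rng = np.random.default_rng(300)
        for _ in range(10):
            table, names = random_integer_cohort(rng, n_markers=2, n_subjects=30)
            sens = []
            for min_spec in (0.6, 0.8, 0.95):
                panel = optimize_panel(table, names, OptimizerConfig(min_specificity=min_spec))
                if not panel.feasible:
                    break
                sens.append(panel.training_performance.sensitivity)
            assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_too_few_complete_cases_rejected(self):
        markers = [MarkerDefinition("A", MarkerLevel.PROTEIN, 1.0)]
        table = make_cohort(
            markers,
            [("uca", {"A": 2.0}, {"grade": "unknown"}), ("no_cancer", {"A": 1.0}),
             ("no_cancer", {"A": 0.5})],
        )
        with pytest.raises(UropanelError):
            optimize_panel(table)

    def test_grid_guard_triggers(self):
        table, names = random_integer_cohort(np.random.default_rng(1), 3, 40, support=30)
        cfg = OptimizerConfig(max_candidates_per_marker=None, max_grid_cells=1000)
        with pytest.raises(ConfigurationError, match="grid"):
            optimize_panel(table, names, cfg)


class TestCrossValidate:
    def test_fold_bookkeeping_and_partition(self):
        table, _ = generate_separable_cohort(30, 60, 0.8, 0.9, 2, seed=4)
        cv = cross_validate(table, k=3, repeats=10, seed=5)
        assert len(cv.folds) == 30
        assert len(cv.repeat_means) == 10
        for r in range(10):
            test_ns = [
                f.test_performance.n_used for f in cv.folds if f.repeat == r
            ]
            assert sum(test_ns) == 90  # folds partition the complete-case cohort

    def test_perfectly_separable_cohort_scores_perfectly(self):
        table, _ = generate_separable_cohort(15, 30, 1.0, 1.0, 2, seed=8)
        cv = cross_validate(table, k=3, repeats=2, seed=1)
        assert cv.mean_sensitivity == 1.0
        assert cv.mean_specificity == 1.0

    def test_deterministic_given_seed(self):
        table, _ = generate_separable_cohort(25, 50, 0.7, 0.9, 2, seed=2)
        a = cross_validate(table, k=3, repeats=3, seed=11)
        b = cross_validate(table, k=3, repeats=3, seed=11)
        assert a == b

    def test_stratum_smaller_than_k_rejected(self):
        table, _ = generate_separable_cohort(2, 30, 0.8, 0.9, 1, seed=0)
        with pytest.raises(UropanelError):
            cross_validate(table, k=3, repeats=1, seed=0)
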