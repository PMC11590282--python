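"""Exhaustive score-panel optimization under a specificity constraint, and
stratified repeated k-fold cross-validation of the whole selection procedure.

A *panel* is a subset of markers, one threshold per marker, and an integer
score threshold ``s``. A subject's score is the number of panel markers
whose value meets its threshold; the subject is called positive when the
score is at least ``s``. The optimizer enumerates every marker subset (up
to a size limit), every combination of data-driven candidate thresholds,
and every ``s``, and returns the panel with the highest training
sensitivity among those whose training specificity satisfies the
constraint (default: at least 95%).

Panel search and evaluation are complete-case over the *candidate* marker
set: a subject missing any candidate marker is excluded up front, so every
panel is compared on the same subjects and a selected panel never produces
unclassified subjects on that set.

Because several panels routinely tie on (sensitivity, specificity), ties
are resolved by a fixed, documented ordering: higher specificity, fewer
markers, lower score threshold, lexicographically earlier marker names,
lower thresholds. This makes the search — and hence cross-validation —
fully deterministic.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort import CohortTable, case_control_labels
from .errors import ConfigurationError, UropanelError
from .metrics import ClassificationStatus, PerformanceSummary

__all__ = [
    "Panel",
    "OptimizerConfig",
    "CVResult",
    "FoldResult",
    "candidate_thresholds",
    "score_subject",
    "optimize_panel",
    "cross_validate",
]


@dataclass(frozen=True)
class Panel:
    """An optimized marker panel: thresholds plus an integer score cutoff."""

    markers: tuple[str, ...]
    thresholds: tuple[float, ...]
    score_threshold: int
    training_performance: PerformanceSummary | None = None
    feasible: bool = True

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.thresholds) or not self.markers:
            raise ConfigurationError("panel needs one threshold per marker and at least one marker")
        if not 1 <= self.score_threshold <= len(self.markers):
            raise ConfigurationError(
                f"score threshold {self.score_threshold} outside 1..{len(self.markers)}"
            )


@dataclass(frozen=True)
class OptimizerConfig:
    """Search configuration.

    ``max_candidates_per_marker`` caps the per-marker candidate threshold
    list by an evenly spaced subsample, bounding the exhaustive grid; with
    the default cap of 8 a five-marker search stays around 10^5 threshold
    combinations. ``max_grid_cells`` is a hard guard against accidentally
    huge grids (cells = threshold combinations x subjects).
    """

    min_specificity: float = 0.95
    max_panel_size: int = 5
    max_candidates_per_marker: int | None = 8
    candidate_policy: str = "roc_corners"
    max_grid_cells: int = 200_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.min_specificity <= 1.0:
            raise ConfigurationError("min_specificity must lie in (0, 1]")
        if self.max_panel_size < 1:
            raise ConfigurationError("max_panel_size must be >= 1")
        if self.candidate_policy != "roc_corners":
            raise ConfigurationError(f"unknown candidate policy {self.candidate_policy!r}")
        if self.max_candidates_per_marker is not None and self.max_candidates_per_marker < 1:
            raise ConfigurationError("max_candidates_per_marker must be >= 1 or None")


def candidate_thresholds(
    values: Sequence[float | None], labels: Sequence[bool]
) -> list[float]:
    """Candidate cutoffs for one marker: the ROC corner points.

    These are the midpoints between consecutive distinct observed values
    whose class composition differs — exactly the thresholds at which the
    empirical ROC curve turns, so no other cutoff can achieve a distinct
    (sensitivity, specificity) pair. Missing values are ignored. If only
    one class is present among the observed values, the list is empty and a
    warning is issued.
    """
    obs: dict[float, set[bool]] = {}
    for v, is_case in zip(values, labels):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        obs.setdefault(float(v), set()).add(bool(is_case))
    classes = set().union(*obs.values()) if obs else set()
    if len(classes) < 2:
        warnings.warn("candidate_thresholds: only one class observed; no candidates")
        return []
    distinct = sorted(obs)
    out = []
    for lo, hi in zip(distinct, distinct[1:]):
        if obs[lo] != obs[hi]:
            out.append((lo + hi) / 2.0)
    return out


def _capped(candidates: list[float], cap: int | None) -> list[float]:
    if cap is None or len(candidates) <= cap:
        return candidates
    idx = np.unique(np.linspace(0, len(candidates) - 1, cap).round().astype(int))
    return [candidates[i] for i in idx]


def score_subject(
    values: Mapping[str, float | None], panel: Panel
) -> tuple[int, ClassificationStatus]:
    """Score one subject against a panel.

    The score counts panel markers whose (present) value meets the panel
    threshold. A subject missing *any* panel marker is unclassified
    regardless of the other markers (complete-case rule); otherwise the
    call is positive iff score >= the panel's score threshold.
    """
    score = 0
    missing = False
    for name, threshold in zip(panel.markers, panel.thresholds):
        v = values.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            missing = True
            continue
        if v >= threshold:
            score += 1
    if missing:
        return score, ClassificationStatus.UNCLASSIFIED
    status = (
        ClassificationStatus.POSITIVE
        if score >= panel.score_threshold
        else ClassificationStatus.NEGATIVE
    )
    return score, status


@dataclass(frozen=True)
class _Candidate:
    sensitivity: float
    specificity: float
    markers: tuple[str, ...]
    thresholds: tuple[float, ...]
    s: int
    tp: int
    tn: int

    def selection_key(self):
        # maximize sensitivity, then the documented tie-break chain
        return (
            -self.sensitivity,
            -self.specificity,
            len(self.markers),
            self.s,
            self.markers,
            self.thresholds,
        )

    def fallback_key(self):
        # when nothing is feasible: maximize specificity, then sensitivity
        return (
            -self.specificity,
            -self.sensitivity,
            len(self.markers),
            self.s,
            self.markers,
            self.thresholds,
        )


def _complete_case_arrays(
    table: CohortTable, marker_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    names = sorted(marker_names)
    X = table.values_matrix(names)
    y = case_control_labels(table)
    complete = ~np.isnan(X).any(axis=1)
    return X[complete], y[complete]


def optimize_panel(
    table: CohortTable,
    markers: Sequence[str] | None = None,
    config: OptimizerConfig | None = None,
) -> Panel:
    """Exhaustive panel search on a cohort (see module docstring).

    ``markers`` defaults to every marker declared in the cohort. If no
    panel reaches the specificity constraint on the training data, the
    panel with the highest specificity (ties toward higher sensitivity) is
    returned with ``feasible=False``.
    """
    config = config or OptimizerConfig()
    names = sorted(markers if markers is not None else table.marker_names)
    for n in names:
        table.marker(n)
    X, y = _complete_case_arrays(table, names)
    return _optimize_arrays(X, y, names, config)


def _optimize_arrays(
    X: np.ndarray, y: np.ndarray, names: Sequence[str], config: OptimizerConfig
) -> Panel:
    n_cases = int(y.sum())
    n_controls = int((~y).sum())
    if n_cases < 2 or n_controls < 2:
        raise UropanelError(
            "panel optimization requires at least 2 complete-case cases and controls "
            f"(got {n_cases} cases, {n_controls} controls)"
        )
    cands: dict[str, list[float]] = {}
    for j, name in enumerate(names):
        cj = _capped(candidate_thresholds(X[:, j], y), config.max_candidates_per_marker)
        if cj:
            cands[name] = cj
    usable = [n for n in names if n in cands]
    if not usable:
        raise UropanelError("no marker has any candidate threshold (degenerate cohort)")

    y_int = y.astype(np.int64)
    best_feasible: _Candidate | None = None
    best_any: _Candidate | None = None
    for size in range(1, min(config.max_panel_size, len(usable)) + 1):
        for subset in itertools.combinations(usable, size):
            cols = [names.index(n) for n in subset]
            cand_lists = [cands[n] for n in subset]
            n_cells = int(np.prod([len(c) for c in cand_lists])) * X.shape[0]
            if n_cells > config.max_grid_cells:
                raise ConfigurationError(
                    f"candidate grid for subset {subset} would need {n_cells} cells; "
                    "lower max_candidates_per_marker or max_panel_size"
                )
            for feas, fallback in _best_per_subset(
                X[:, cols], y_int, subset, cand_lists, config.min_specificity
            ):
                if feas is not None and (
                    best_feasible is None or feas.selection_key() < best_feasible.selection_key()
                ):
                    best_feasible = feas
                if best_any is None or fallback.fallback_key() < best_any.fallback_key():
                    best_any = fallback

    chosen = best_feasible if best_feasible is not None else best_any
    assert chosen is not None
    return Panel(
        markers=chosen.markers,
        thresholds=chosen.thresholds,
        score_threshold=chosen.s,
        training_performance=PerformanceSummary(
            n_cases_used=n_cases,
            n_controls_used=n_controls,
            sensitivity=chosen.sensitivity,
            specificity=chosen.specificity,
        ),
        feasible=best_feasible is not None,
    )


def _best_per_subset(
    Xsub: np.ndarray,
    y_int: np.ndarray,
    subset: tuple[str, ...],
    cand_lists: list[list[float]],
    min_specificity: float,
) -> list[tuple[_Candidate | None, _Candidate]]:
    """Best candidates per score threshold for one marker subset.

    Builds the full score tensor over the threshold grid by broadcasting
    marker-wise indicator arrays, then reduces it per score threshold. For
    each ``s`` two grid cells are kept: the best *feasible* cell
    (specificity meets the constraint; maximizing sensitivity, then
    specificity, then lowest thresholds) and the best *fallback* cell
    (maximizing specificity, then sensitivity). This reduction is lossless
    with respect to the global selection and its tie-breaks.
    """
    k = len(subset)
    n = Xsub.shape[0]
    n_cases = int(y_int.sum())
    n_controls = n - n_cases
    shape = tuple(len(c) for c in cand_lists)
    score = np.zeros(shape + (n,), dtype=np.int8)
    for j, clist in enumerate(cand_lists):
        ind = (Xsub[:, j][None, :] >= np.asarray(clist)[:, None]).astype(np.int8)
        bshape = [1] * k + [n]
        bshape[j] = len(clist)
        score += ind.reshape(bshape)
    flat = score.reshape(-1, n)
    grids = np.meshgrid(*[np.asarray(c) for c in cand_lists], indexing="ij")
    thr_flat = [g.reshape(-1) for g in grids]

    def cell(idx: int, sens: np.ndarray, spec: np.ndarray, tp: np.ndarray, s: int) -> _Candidate:
        return _Candidate(
            sensitivity=float(sens[idx]),
            specificity=float(spec[idx]),
            markers=subset,
            thresholds=tuple(float(t[idx]) for t in thr_flat),
            s=s,
            tp=int(tp[idx]),
            tn=int(round(spec[idx] * n_controls)),
        )

    out: list[tuple[_Candidate | None, _Candidate]] = []
    for s in range(1, k + 1):
        pos = flat >= s
        tp = pos @ y_int
        fp = pos.sum(axis=1) - tp
        sens = tp / n_cases
        spec = (n_controls - fp) / n_controls
        thr_keys = tuple(reversed(thr_flat))  # lexsort: last key is primary
        fallback_idx = int(np.lexsort(thr_keys + (-sens, -spec))[0])
        fallback = cell(fallback_idx, sens, spec, tp, s)
        feasible = None
        ok = np.flatnonzero(spec >= min_specificity)
        if ok.size:
            sub_keys = tuple(t[ok] for t in thr_keys) + (-spec[ok], -sens[ok])
            feas_idx = int(ok[np.lexsort(sub_keys)[0]])
            feasible = cell(feas_idx, sens, spec, tp, s)
        out.append((feasible, fallback))
    return out


@dataclass(frozen=True)
class FoldResult:
    repeat: int
    fold: int
    panel: Panel
    test_performance: PerformanceSummary


@dataclass(frozen=True)
class CVResult:
    """Stratified repeated k-fold cross-validation of panel selection.

    ``mean_sensitivity``/``mean_specificity`` average the held-out
    performance over all k x repeats fold evaluations; ``repeat_means``
    additionally gives the per-repeat averages (mean over each repeat's k
    folds), since "mean across test sets" admits either reading.
    """

    folds: tuple[FoldResult, ...]
    mean_sensitivity: float
    mean_specificity: float
    repeat_means: tuple[tuple[float, float], ...]  # (sensitivity, specificity) per repeat
    k: int
    repeats: int


def cross_validate(
    table: CohortTable,
    markers: Sequence[str] | None = None,
    config: OptimizerConfig | None = None,
    k: int = 3,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified ``repeats x k``-fold cross-validation of the optimizer.

    The complete-case cohort is split into ``k`` folds preserving the
    case/control ratio (fold sizes differ by at most one within each
    class). For every fold, a panel is selected on the remaining training
    folds with :func:`optimize_panel` and evaluated on the held-out fold.
    Deterministic given the seed.
    """
    config = config or OptimizerConfig()
    names = sorted(markers if markers is not None else table.marker_names)
    X, y = _complete_case_arrays(table, names)
    case_idx = np.flatnonzero(y)
    ctrl_idx = np.flatnonzero(~y)
    if len(case_idx) < k or len(ctrl_idx) < k:
        raise UropanelError(
            f"each class needs at least k={k} complete-case members "
            f"(got {len(case_idx)} cases, {len(ctrl_idx)} controls)"
        )
    rng = np.random.default_rng(seed)
    folds: list[FoldResult] = []
    repeat_means = []
    for r in range(repeats):
        case_folds = np.array_split(rng.permutation(case_idx), k)
        ctrl_folds = np.array_split(rng.permutation(ctrl_idx), k)
        per_repeat = []
        for f in range(k):
            test = np.concatenate([case_folds[f], ctrl_folds[f]])
            train = np.concatenate(
                [case_folds[i] for i in range(k) if i != f]
                + [ctrl_folds[i] for i in range(k) if i != f]
            )
            panel = _optimize_arrays(X[train], y[train], names, config)
            perf = _evaluate_panel_arrays(X[test], y[test], names, panel)
            folds.append(FoldResult(repeat=r, fold=f, panel=panel, test_performance=perf))
            per_repeat.append(perf)
        repeat_means.append(
            (
                float(np.mean([p.sensitivity for p in per_repeat])),
                float(np.mean([p.specificity for p in per_repeat])),
            )
        )
    return CVResult(
        folds=tuple(folds),
        mean_sensitivity=float(np.mean([f.test_performance.sensitivity for f in folds])),
        mean_specificity=float(np.mean([f.test_performance.specificity for f in folds])),
        repeat_means=tuple(repeat_means),
        k=k,
        repeats=repeats,
    )


def _evaluate_panel_arrays(
    X: np.ndarray, y: np.ndarray, names: Sequence[str], panel: Panel
) -> PerformanceSummary:
    cols = [list(names).index(m) for m in panel.markers]
    thr = np.asarray(panel.thresholds)
    score = (X[:, cols] >= thr[None, :]).sum(axis=1)
    pos = score >= panel.score_threshold
    n_cases = int(y.sum())
    n_controls = int((~y).sum())
    if n_cases == 0 or n_controls == 0:
        raise UropanelError("panel evaluation requires both classes")
    tp = int(np.count_nonzero(pos & y))
    tn = int(np.count_nonzero(~pos & ~y))
    return PerformanceSummary(
        n_cases_used=n_cases,
        n_controls_used=n_controls,
        sensitivity=tp / n_cases,
        specificity=tn / n_controls,
    )
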