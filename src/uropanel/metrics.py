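"""Single-marker diagnostics: fixed-cutoff classification, sensitivity and
specificity with the missing-data exclusion rule, ROC/AUC, percentile and
specificity-constrained threshold selection, and the Wilcoxon rank-sum test.

Conventions used throughout the package:

* Positivity is ``value >= threshold`` (boundary inclusive).
* A subject whose marker value is absent is *unclassified*: it is removed
  from both the numerator and the denominator of sensitivity/specificity,
  never silently counted as negative.
* ROC operating points sit at the observed values themselves (one point per
  distinct value, plus a +inf point where nothing is called positive), so the
  curve is exactly consistent with the classification rule above.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohort import MarkerDefinition
from .errors import InfeasibleConstraintError, UndefinedMetricError, UropanelError

__all__ = [
    "ClassificationStatus",
    "PerformanceSummary",
    "RocCurve",
    "normalize_to_creatinine",
    "classify_marker",
    "classify_values",
    "performance",
    "percentile_threshold",
    "roc_curve",
    "threshold_at_min_specificity",
    "wilcoxon_rank_sum",
    "bootstrap_auc_ci",
]


class ClassificationStatus(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PerformanceSummary:
    """Sensitivity/specificity together with the denominators actually used.

    ``sensitivity * n_cases_used`` and ``specificity * n_controls_used`` are
    integer counts by construction; the raw counts are kept so reports can
    re-derive exact ratios.
    """

    n_cases_used: int
    n_controls_used: int
    sensitivity: float
    specificity: float

    @property
    def n_used(self) -> int:
        return self.n_cases_used + self.n_controls_used


def normalize_to_creatinine(concentration_pg_per_ml: float, creatinine_mg_per_ml: float) -> float:
    """Creatinine-normalise a urinary analyte concentration.

    Dividing pg/mL by mg/mL corrects for urine dilution and yields pg per mg
    creatinine, the unit in which the protein cutoffs are expressed.
    """
    if creatinine_mg_per_ml <= 0:
        raise UropanelError(
            f"creatinine must be positive (got {creatinine_mg_per_ml} mg/mL); "
            "a non-positive value indicates an invalid urine chemistry record"
        )
    if concentration_pg_per_ml < 0:
        raise UropanelError(f"concentration must be non-negative (got {concentration_pg_per_ml})")
    return concentration_pg_per_ml / creatinine_mg_per_ml


def classify_marker(value: float | None, marker: MarkerDefinition) -> ClassificationStatus:
    """Fixed-cutoff call for one subject: positive iff value >= threshold;
    an absent value leaves the subject unclassified."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ClassificationStatus.UNCLASSIFIED
    if value >= marker.threshold:
        return ClassificationStatus.POSITIVE
    return ClassificationStatus.NEGATIVE


def classify_values(values: Iterable[float | None], marker: MarkerDefinition) -> list[ClassificationStatus]:
    return [classify_marker(v, marker) for v in values]


def performance(
    statuses: Sequence[ClassificationStatus], labels: Sequence[bool]
) -> PerformanceSummary:
    """Sensitivity/specificity over the classified subjects only.

    Unclassified subjects are excluded from both the numerator and the
    denominator. An empty classified case (or control) set raises
    :class:`UndefinedMetricError` rather than reporting a silent 0/0.
    """
    if len(statuses) != len(labels):
        raise UropanelError("statuses and labels must be aligned")
    tp = fn = tn = fp = 0
    for status, is_case in zip(statuses, labels):
        if status is ClassificationStatus.UNCLASSIFIED:
            continue
        pos = status is ClassificationStatus.POSITIVE
        if is_case:
            tp += pos
            fn += not pos
        else:
            fp += pos
            tn += not pos
    n_cases = tp + fn
    n_controls = tn + fp
    if n_cases == 0:
        raise UndefinedMetricError("no classified cases: sensitivity is undefined")
    if n_controls == 0:
        raise UndefinedMetricError("no classified controls: specificity is undefined")
    return PerformanceSummary(
        n_cases_used=n_cases,
        n_controls_used=n_controls,
        sensitivity=tp / n_cases,
        specificity=tn / n_controls,
    )


def percentile_threshold(control_values: Sequence[float], q: float) -> float:
    """Nearest-rank percentile of the control distribution.

    Returns the ``ceil(q * n)``-th order statistic, so at least a
    q-fraction of the defining controls lie at or below it. Under
    >=-positivity the controls at the returned value itself are called
    positive, so specificity on the defining sample is at least
    ``q - k/n`` where ``k`` counts the controls tied at that value
    (``q - 1/n`` when values are distinct).
    """
    values = [v for v in control_values if v is not None and not math.isnan(v)]
    if not values:
        raise UropanelError("percentile_threshold requires at least one control value")
    if not 0.0 < q <= 1.0:
        raise UropanelError(f"q must lie in (0, 1] (got {q})")
    ordered = sorted(values)
    rank = math.ceil(q * len(ordered))  # 1-based nearest rank
    return ordered[rank - 1]


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points and trapezoid AUC.

    ``points`` is ordered by decreasing threshold starting at +inf, so
    sensitivity is non-decreasing and specificity non-increasing along the
    array; the endpoints attain (sens, spec) = (0, 1) and (1, 0).
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def __iter__(self):
        return iter(zip(self.thresholds, self.sensitivities, self.specificities))


def roc_curve(values: Sequence[float | None], labels: Sequence[bool]) -> RocCurve:
    """Empirical ROC curve of one marker (absent values excluded first).

    One operating point per distinct observed value (threshold equal to that
    value, >=-positivity) plus a +inf point; AUC by the trapezoid rule over
    (1 - specificity, sensitivity), which for this construction equals the
    tie-adjusted Mann-Whitney probability.
    """
    vals, labs = [], []
    for v, is_case in zip(values, labels):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        vals.append(float(v))
        labs.append(bool(is_case))
    v = np.asarray(vals)
    y = np.asarray(labs)
    n_cases = int(y.sum())
    n_controls = int((~y).sum())
    if n_cases == 0 or n_controls == 0:
        raise UndefinedMetricError("ROC requires at least one case and one control with values")

    thresholds = np.concatenate(([np.inf], np.unique(v)[::-1]))
    # counts of subjects >= t for each threshold
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    case_vals = v[y]
    ctrl_vals = v[~y]
    for i, t in enumerate(thresholds):
        sens[i] = np.count_nonzero(case_vals >= t) / n_cases
        spec[i] = np.count_nonzero(ctrl_vals < t) / n_controls
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def threshold_at_min_specificity(
    curve: RocCurve, min_specificity: float
) -> tuple[float, PerformanceSummary]:
    """Best operating point with specificity at least ``min_specificity``.

    Among qualifying points the one with maximal sensitivity is returned;
    ties are broken toward higher specificity and then higher threshold,
    reflecting the study's priority on specificity.
    """
    if not 0.0 < min_specificity <= 1.0:
        raise UropanelError(f"min_specificity must lie in (0, 1] (got {min_specificity})")
    best = None
    for t, sens, spec in curve:
        if spec < min_specificity:
            continue
        key = (sens, spec, t)
        if best is None or key > best:
            best = key
    if best is None:
        raise InfeasibleConstraintError(
            f"no operating point reaches specificity >= {min_specificity}"
        )
    sens, spec, t = best[0], best[1], best[2]
    return float(t), PerformanceSummary(
        n_cases_used=curve.n_cases,
        n_controls_used=curve.n_controls,
        sensitivity=float(sens),
        specificity=float(spec),
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of ``x``, p).

    Mid-ranks handle ties. ``method='exact'`` enumerates the permutation
    distribution of the rank sum (intended for up to ~10 observations per
    group); ``method='normal'`` uses the normal approximation with
    tie-corrected variance and a 0.5 continuity correction. ``'auto'``
    switches to the exact test when both groups have at most 10 values.
    When every pooled value is identical the p-value is 1 by convention.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise UropanelError("both samples must be non-empty")
    if method not in ("auto", "exact", "normal"):
        raise UropanelError(f"unknown method {method!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    if method == "exact" or (method == "auto" and max(n, m) <= 25):
        return w, _exact_rank_sum_p(ranks, n, w)
    return w, _normal_rank_sum_p(pooled, ranks, n, m, w)


def _exact_rank_sum_p(ranks: np.ndarray, n: int, w: float) -> float:
    """Exact two-sided p over all C(N, n) group assignments (doubled smaller
    tail, capped at 1).

    The permutation distribution of the rank sum is computed by a
    subset-sum count over doubled mid-ranks (integers), so the result is
    exact even under ties, without enumerating combinations one by one.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    total_sum = int(r2.sum())
    # counts[k, s] = number of k-subsets of ranks with doubled rank-sum s
    counts = np.zeros((n + 1, total_sum + 1))
    counts[0, 0] = 1.0
    for r in r2:
        for k in range(n, 0, -1):  # descending so each rank enters once
            counts[k, r:] += counts[k - 1, : total_sum + 1 - r]
    dist = counts[n]
    total = dist.sum()
    w2 = int(round(2 * w))
    le = dist[: w2 + 1].sum()
    ge = dist[w2:].sum()
    return min(1.0, 2.0 * min(le, ge) / total)


def _normal_rank_sum_p(pooled: np.ndarray, ranks: np.ndarray, n: int, m: int, w: float) -> float:
    big_n = n + m
    mean = n * (big_n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return 1.0
    # continuity correction shrinks |w - mean| by 0.5
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * stats.norm.sf(z))


def bootstrap_auc_ci(
    values: Sequence[float | None],
    labels: Sequence[bool],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the ROC AUC.

    Cases and controls are resampled independently (stratified bootstrap).
    This is a generic bootstrap interval, labelled as such in reports.
    """
    vals, labs = [], []
    for v, is_case in zip(values, labels):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        vals.append(float(v))
        labs.append(bool(is_case))
    v = np.asarray(vals)
    y = np.asarray(labs)
    cases = v[y]
    ctrls = v[~y]
    if cases.size == 0 or ctrls.size == 0:
        raise UndefinedMetricError("bootstrap AUC requires both classes")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(cases, cases.size, replace=True)
        ks = rng.choice(ctrls, ctrls.size, replace=True)
        # Mann-Whitney probability, equivalent to the trapezoid AUC
        u = stats.mannwhitneyu(cs, ks, alternative="two-sided").statistic
        aucs[b] = u / (cs.size * ks.size)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1.0 - alpha))
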