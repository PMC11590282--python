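"""Synthetic cohort generation.

The real verification cohort is not publicly deposited, so this module
generates cohorts with the statistical structure the downstream analysis
assumes: three diagnostic groups (urothelial carcinoma, other genitourinary
or gynecologic cancer, no cancer) whose per-marker distributions are
calibrated to the published group medians and to the single-marker
sensitivity/specificity observed at the fixed study cutoffs, covariate
margins matching the published cohort description, and marker-wise
missing-completely-at-random gaps.

Distribution families: methylation fractions follow Beta distributions
(support respects [0, 1]); creatinine-normalised protein concentrations
follow log-normals (strictly positive, right-skewed). Each family has two
free parameters, which are pinned down by two published facts per marker
and group: the group median and the probability of exceeding the study
cutoff (i.e. the reported sensitivity or one minus the reported
specificity).

Everything is driven by a single explicitly-seeded generator: identical
seed and configuration give byte-identical cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .cohort import (
    DEFAULT_MARKERS,
    AgeBand,
    CohortTable,
    ErythrocyteBand,
    Grade,
    Group,
    LeukocyteBand,
    MarkerDefinition,
    MarkerLevel,
    Sex,
    SubjectRecord,
    UcaHistory,
)
from .errors import ConfigurationError

__all__ = [
    "BetaDist",
    "LogNormalDist",
    "MixtureDist",
    "MarkerModel",
    "SubcohortSpec",
    "CohortConfig",
    "beta_from_median_tail",
    "lognormal_from_median_tail",
    "default_cohort_config",
    "generate_cohort",
    "generate_separable_cohort",
]


class BetaDist:
    """Beta distribution on [0, 1] for methylation fractions."""

    def __init__(self, a: float, b: float) -> None:
        if a <= 0 or b <= 0:
            raise ConfigurationError(f"Beta parameters must be positive (got a={a}, b={b})")
        self.a = float(a)
        self.b = float(b)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return stats.beta.ppf(u, self.a, self.b)

    def median(self) -> float:
        return float(stats.beta.ppf(0.5, self.a, self.b))

    def sf(self, x: float) -> float:
        return float(stats.beta.sf(x, self.a, self.b))

    def __repr__(self) -> str:
        return f"BetaDist(a={self.a:.4g}, b={self.b:.4g})"


class LogNormalDist:
    """Log-normal distribution for creatinine-normalised protein levels."""

    def __init__(self, mu: float, sigma: float) -> None:
        if sigma <= 0:
            raise ConfigurationError(f"log-normal sigma must be positive (got {sigma})")
        self.mu = float(mu)
        self.sigma = float(sigma)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return np.exp(self.mu + self.sigma * stats.norm.ppf(u))

    def median(self) -> float:
        return math.exp(self.mu)

    def sf(self, x: float) -> float:
        if x <= 0:
            return 1.0
        return float(stats.norm.sf((math.log(x) - self.mu) / self.sigma))

    def __repr__(self) -> str:
        return f"LogNormalDist(mu={self.mu:.4g}, sigma={self.sigma:.4g})"


class MixtureDist:
    """Finite mixture of component distributions (weights sum to 1)."""

    def __init__(self, components: Sequence[tuple[float, object]]) -> None:
        weights = np.array([w for w, _ in components], dtype=float)
        if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
            raise ConfigurationError("mixture weights must be non-negative and sum to 1")
        self.components = [(float(w), d) for w, d in components]

    def cdf(self, x: float) -> float:
        return sum(w * (1.0 - d.sf(x)) for w, d in self.components)

    def sf(self, x: float) -> float:
        return sum(w * d.sf(x) for w, d in self.components)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        lo, hi = 0.0, 1.0
        # bracket from component quantiles
        los = [float(np.min(d.ppf(np.array([1e-9])))) for _, d in self.components]
        his = [float(np.max(d.ppf(np.array([1.0 - 1e-9])))) for _, d in self.components]
        lo, hi = min(los), max(his)
        out = np.empty_like(u)
        for i, ui in enumerate(u):
            out[i] = optimize.brentq(lambda x: self.cdf(x) - ui, lo, hi, xtol=1e-10)
        return out

    def median(self) -> float:
        return float(self.ppf(np.array([0.5]))[0])

    def __repr__(self) -> str:
        inner = ", ".join(f"{w:.3f}*{d!r}" for w, d in self.components)
        return f"MixtureDist({inner})"


def beta_from_median_tail(median: float, threshold: float, tail_prob: float) -> BetaDist:
    """Beta distribution with the given median and P(X >= threshold).

    For a fixed concentration ``kappa = a + b`` the shape ``a`` matching the
    median is found by bisection; the concentration is then chosen so the
    upper-tail mass beyond the cutoff matches ``tail_prob`` (the tail is
    monotone in the concentration when the cutoff lies above the median).
    """
    if not 0.0 < median < 1.0:
        raise ConfigurationError(f"median must lie strictly in (0, 1) (got {median})")
    if not 0.0 < threshold < 1.0 or not 0.0 < tail_prob < 1.0:
        raise ConfigurationError("threshold and tail_prob must lie in (0, 1)")
    if threshold <= median:
        raise ConfigurationError("cutoff must lie above the median for this calibration")

    def a_for_kappa(kappa: float) -> float:
        f = lambda a: stats.beta.ppf(0.5, a, kappa - a) - median
        return optimize.brentq(f, 1e-9 * kappa, (1.0 - 1e-9) * kappa, xtol=1e-12)

    def tail_gap(kappa: float) -> float:
        a = a_for_kappa(kappa)
        return float(stats.beta.sf(threshold, a, kappa - a)) - tail_prob

    lo, hi = 0.05, 5.0
    while tail_gap(hi) > 0 and hi < 1e6:
        hi *= 2.0
    while tail_gap(lo) < 0 and lo > 1e-6:
        lo /= 2.0
    kappa = optimize.brentq(tail_gap, lo, hi, xtol=1e-10)
    a = a_for_kappa(kappa)
    return BetaDist(a, kappa - a)


def lognormal_from_median_tail(median: float, threshold: float, tail_prob: float) -> LogNormalDist:
    """Log-normal with the given median and P(X >= threshold) (closed form)."""
    if median <= 0 or threshold <= 0:
        raise ConfigurationError("median and threshold must be positive")
    if not 0.0 < tail_prob < 1.0:
        raise ConfigurationError("tail_prob must lie in (0, 1)")
    if math.isclose(threshold, median):
        raise ConfigurationError("cutoff equal to the median leaves the shape unidentified")
    mu = math.log(median)
    z = stats.norm.isf(tail_prob)
    sigma = (math.log(threshold) - mu) / z
    if sigma <= 0:
        raise ConfigurationError(
            "inconsistent calibration: tail mass must be below 0.5 iff the cutoff "
            "exceeds the median"
        )
    return LogNormalDist(mu, sigma)


@dataclass(frozen=True)
class MarkerModel:
    """One marker's generating distribution within a group, plus its
    missingness rate (missing completely at random, independent per marker)."""

    distribution: object
    missingness_rate: float = 0.0
    target_median: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ConfigurationError(
                f"missingness_rate must lie in [0, 1] (got {self.missingness_rate})"
            )


@dataclass(frozen=True)
class SubcohortSpec:
    """A homogeneous block of subjects: one diagnostic group with exact
    covariate category counts and per-marker generating models.

    ``covariates`` maps a covariate field name to a mapping of category
    value -> exact count; every provided covariate must sum to ``n``.
    Covariates are assigned independently of each other (each column is an
    independent permutation), which reproduces published margins but no
    joint covariate structure.
    """

    name: str
    group: Group
    n: int
    marker_models: Mapping[str, MarkerModel]
    covariates: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"subcohort {self.name!r}: n must be >= 0")
        for cov, counts in self.covariates.items():
            total = sum(counts.values())
            if total != self.n:
                raise ConfigurationError(
                    f"subcohort {self.name!r}: covariate {cov!r} counts sum to {total}, "
                    f"expected n={self.n}"
                )


_COVARIATE_ENUMS = {
    "sex": Sex,
    "age_band": AgeBand,
    "leukocyte_band": LeukocyteBand,
    "erythrocyte_band": ErythrocyteBand,
    "uca_history": UcaHistory,
    "grade": Grade,
}


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    markers: tuple[MarkerDefinition, ...]
    subcohorts: tuple[SubcohortSpec, ...]
    seed: int = 0
    rank_correlation: float = 0.0  # Gaussian-copula correlation across markers

    def __post_init__(self) -> None:
        if sum(s.n for s in self.subcohorts) <= 0:
            raise ConfigurationError("total cohort size must be positive")
        if not -0.99 <= self.rank_correlation <= 0.99:
            raise ConfigurationError("rank_correlation must lie in [-0.99, 0.99]")
        names = {m.name for m in self.markers}
        for sub in self.subcohorts:
            missing = set(sub.marker_models) - names
            if missing:
                raise ConfigurationError(
                    f"subcohort {sub.name!r} models undeclared markers {sorted(missing)}"
                )
            for cov in sub.covariates:
                if cov not in _COVARIATE_ENUMS:
                    raise ConfigurationError(f"unknown covariate {cov!r}")


# --- Default configuration -------------------------------------------------
#
# Calibration facts (group median, and probability of exceeding the study
# cutoff) per marker. Methylation refers to the male low-leukocyte analysis
# population; proteins to the full mixed-sex collective. The "other cancer"
# group shares the cancer-free distributions except for a CXCL16 elevation
# in a kidney-cancer subgroup.
#
# Default per-marker MCAR rates are calibrated to the published
# complete-case fractions over the five markers: 65/71 of cases and
# 878/1048 of non-cases have all five values, so the per-marker rate is
# 1 - (fraction complete)^(1/5) per group.

_MISSING_RATE_BY_GROUP = {
    Group.UCA: 1.0 - (65 / 71) ** 0.2,           # ~0.0176
    Group.OTHER_CANCER: 1.0 - (878 / 1048) ** 0.2,  # ~0.0348
    Group.NO_CANCER: 1.0 - (878 / 1048) ** 0.2,
}

_UCA_N, _OTHER_N, _NOCANCER_N = 71, 207, 841
_KIDNEY_FRACTION = 40 / 207  # kidney-cancer share of the other-cancer group


def _default_marker_models() -> dict[Group, dict[str, MarkerModel]]:
    # methylation: (median, tail beyond cutoff) per group
    control_meth = {
        "ALOX5": beta_from_median_tail(0.08, 0.435, 1 - 0.9545),
        "TRPS1": beta_from_median_tail(0.12, 0.465, 1 - 0.9805),
        "Chr16": beta_from_median_tail(0.21, 0.555, 1 - 0.9825),
    }
    uca_meth = {
        "ALOX5": beta_from_median_tail(0.33, 0.435, 0.3962),
        "TRPS1": beta_from_median_tail(0.33, 0.465, 0.2963),
        "Chr16": beta_from_median_tail(0.37, 0.555, 0.2778),
    }
    ctrl_cxcl16 = lognormal_from_median_tail(174.3, 648.52, 1 - 0.9416)
    ctrl_tgfbi = lognormal_from_median_tail(365.8, 1345.97, 1 - 0.8584)
    uca_cxcl16 = lognormal_from_median_tail(372.9, 648.52, 0.3099)
    uca_tgfbi = lognormal_from_median_tail(1730.2, 1345.97, 0.5634)
    # kidney-cancer CXCL16 runs mildly above the cancer-free level
    kidney_cxcl16 = LogNormalDist(math.log(328.1), ctrl_cxcl16.sigma)
    other_cxcl16 = MixtureDist(
        [(1.0 - _KIDNEY_FRACTION, ctrl_cxcl16), (_KIDNEY_FRACTION, kidney_cxcl16)]
    )

    def model(group, dist, median=None):
        return MarkerModel(
            dist, missingness_rate=_MISSING_RATE_BY_GROUP[group], target_median=median
        )

    uca, oth, noc = Group.UCA, Group.OTHER_CANCER, Group.NO_CANCER
    return {
        uca: {
            "ALOX5": model(uca, uca_meth["ALOX5"], 0.33),
            "TRPS1": model(uca, uca_meth["TRPS1"], 0.33),
            "Chr16": model(uca, uca_meth["Chr16"], 0.37),
            "CXCL16": model(uca, uca_cxcl16, 372.9),
            "TGFBI": model(uca, uca_tgfbi, 1730.2),
        },
        oth: {
            "ALOX5": model(oth, control_meth["ALOX5"], 0.08),
            "TRPS1": model(oth, control_meth["TRPS1"], 0.12),
            "Chr16": model(oth, control_meth["Chr16"], 0.21),
            "CXCL16": model(oth, other_cxcl16),
            "TGFBI": model(oth, ctrl_tgfbi, 365.8),
        },
        noc: {
            "ALOX5": model(noc, control_meth["ALOX5"], 0.08),
            "TRPS1": model(noc, control_meth["TRPS1"], 0.12),
            "Chr16": model(noc, control_meth["Chr16"], 0.21),
            "CXCL16": model(noc, ctrl_cxcl16, 174.3),
            "TGFBI": model(noc, ctrl_tgfbi, 365.8),
        },
    }


#: Exact covariate margins of the published cohort description
#: (full protein collective, N = 1119).
_DEFAULT_COVARIATES: dict[Group, dict[str, dict[str, int]]] = {
    Group.UCA: {
        "sex": {"male": 62, "female": 9},
        "age_band": {"lt70": 33, "ge70": 38},
        "leukocyte_band": {"neg": 39, "b25": 12, "b100": 15, "b500": 5},
        "erythrocyte_band": {"neg": 28, "b10": 5, "b25": 4, "b50": 10, "b250": 24},
        "uca_history": {"no": 33, "yes": 38},
        "grade": {"low": 28, "high": 16, "unknown": 27},
    },
    Group.OTHER_CANCER: {
        "sex": {"male": 118, "female": 89},
        "age_band": {"lt70": 125, "ge70": 79, "unknown": 3},
        "leukocyte_band": {"neg": 142, "b10": 1, "b25": 21, "b100": 21, "b500": 20, "unknown": 2},
        "erythrocyte_band": {"neg": 147, "b10": 22, "b25": 10, "b50": 12, "b250": 14, "unknown": 2},
        "uca_history": {"no": 200, "yes": 5, "unknown": 2},
        "grade": {"not_applicable": 207},
    },
    Group.NO_CANCER: {
        "sex": {"male": 473, "female": 368},
        "age_band": {"lt70": 508, "ge70": 328, "unknown": 5},
        "leukocyte_band": {"neg": 594, "b25": 88, "b100": 71, "b500": 87, "unknown": 1},
        "erythrocyte_band": {"neg": 511, "b10": 103, "b25": 80, "b50": 56, "b250": 89, "unknown": 2},
        "uca_history": {"no": 786, "yes": 52, "unknown": 3},
        "grade": {"not_applicable": 841},
    },
}


def default_cohort_config(
    seed: int = 0,
    scale: float = 1.0,
    missingness_rate: float | None = None,
) -> CohortConfig:
    """Study-like default configuration (N = 1119 at scale 1).

    ``scale`` multiplies every subcohort size (rounded, minimum 1) for
    quick smaller simulations; covariate counts are scaled proportionally
    with largest-remainder rounding so they still sum to the group size.
    """
    models = _default_marker_models()
    if missingness_rate is not None:
        models = {
            g: {
                name: MarkerModel(m.distribution, missingness_rate, m.target_median)
                for name, m in per.items()
            }
            for g, per in models.items()
        }
    sizes = {Group.UCA: _UCA_N, Group.OTHER_CANCER: _OTHER_N, Group.NO_CANCER: _NOCANCER_N}
    subcohorts = []
    for group, n_full in sizes.items():
        n = max(1, round(n_full * scale))
        covs = {
            cov: _scale_counts(counts, n)
            for cov, counts in _DEFAULT_COVARIATES[group].items()
        }
        subcohorts.append(
            SubcohortSpec(
                name=group.value,
                group=group,
                n=n,
                marker_models=models[group],
                covariates=covs,
            )
        )
    return CohortConfig(markers=DEFAULT_MARKERS, subcohorts=tuple(subcohorts), seed=seed)


def _scale_counts(counts: Mapping[str, int], n: int) -> dict[str, int]:
    """Largest-remainder scaling of category counts to a new total."""
    total = sum(counts.values())
    raw = {k: v * n / total for k, v in counts.items()}
    floored = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(floored.values())
    by_remainder = sorted(counts, key=lambda k: (floored[k] - raw[k], k))
    for k in by_remainder[:short]:
        floored[k] += 1
    return {k: v for k, v in floored.items() if v > 0}


def generate_cohort(config: CohortConfig, seed: int | None = None) -> CohortTable:
    """Draw one cohort from a configuration.

    Deterministic given the seed (``seed`` overrides ``config.seed``).
    Marker values are drawn via each model's quantile function from
    uniforms that are independent across markers by default, or coupled by
    a Gaussian copula when ``config.rank_correlation`` is non-zero.
    Missingness masks are drawn independently per marker.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    marker_names = [m.name for m in config.markers]
    subjects: list[SubjectRecord] = []
    counter = 0
    for sub in config.subcohorts:
        n = sub.n
        cov_columns: dict[str, list[str]] = {}
        for cov, counts in sub.covariates.items():
            enum_cls = _COVARIATE_ENUMS[cov]
            column = [c for cat, k in counts.items() for c in [enum_cls(cat).value] * k]
            cov_columns[cov] = list(rng.permutation(column))
        uniforms = _draw_uniforms(rng, n, len(marker_names), config.rank_correlation)
        values_by_marker: dict[str, np.ndarray] = {}
        missing_by_marker: dict[str, np.ndarray] = {}
        for j, name in enumerate(marker_names):
            model = sub.marker_models.get(name)
            if model is None:
                values_by_marker[name] = np.full(n, np.nan)
                missing_by_marker[name] = np.ones(n, dtype=bool)
                continue
            values_by_marker[name] = np.asarray(model.distribution.ppf(uniforms[:, j]))
            missing_by_marker[name] = rng.random(n) < model.missingness_rate
        for i in range(n):
            counter += 1
            values = {
                name: (None if missing_by_marker[name][i] else float(values_by_marker[name][i]))
                for name in marker_names
            }
            defaults = {"grade": "not_applicable" if sub.group is not Group.UCA else "unknown"}
            fields = {
                cov: cov_columns.get(cov, [defaults.get(cov, "unknown")] * n)[i]
                for cov in _COVARIATE_ENUMS
            }
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{counter:05d}",
                    group=sub.group,
                    values=values,
                    **fields,
                )
            )
    return CohortTable(markers=list(config.markers), subjects=subjects)


def _draw_uniforms(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    if rho == 0.0 or p == 1:
        return rng.random((n, p))
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    return stats.norm.cdf(z)


def generate_separable_cohort(
    n_case: int,
    n_control: int,
    target_sensitivity: float,
    target_specificity: float,
    markers: Sequence[str] | int = 2,
    seed: int = 0,
) -> tuple[CohortTable, dict[str, float]]:
    """Parameter-recovery fixture with known per-marker operating points.

    Each marker independently exceeds its generating threshold with
    probability ``target_sensitivity`` in cases and ``1 -
    target_specificity`` in controls (values uniform on either side of the
    threshold), so classifying at the returned thresholds reproduces the
    targets up to binomial sampling error. With both targets equal to 1 the
    classes are perfectly separated.
    """
    if not 0.0 < target_sensitivity <= 1.0 or not 0.0 < target_specificity <= 1.0:
        raise ConfigurationError("targets must lie in (0, 1]")
    if isinstance(markers, int):
        marker_names = [f"M{i + 1}" for i in range(markers)]
    else:
        marker_names = list(markers)
    if not marker_names:
        raise ConfigurationError("at least one marker is required")
    t = 100.0
    defs = [MarkerDefinition(name, MarkerLevel.PROTEIN, t) for name in marker_names]
    rng = np.random.default_rng(seed)
    subjects = []
    for label, count, p_above in (
        ("case", n_case, target_sensitivity),
        ("ctrl", n_control, 1.0 - target_specificity),
    ):
        for i in range(count):
            values = {}
            for name in marker_names:
                above = rng.random() < p_above
                if above:
                    values[name] = float(rng.uniform(t, 2 * t))
                else:
                    values[name] = float(rng.uniform(0.0, t * (1 - 1e-12)))
            subjects.append(
                SubjectRecord(
                    subject_id=f"{label}{i:05d}",
                    group=Group.UCA if label == "case" else Group.NO_CANCER,
                    values=values,
                )
            )
    table = CohortTable(markers=defs, subjects=subjects)
    return table, {name: t for name in marker_names}
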