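"""Analysis-plan runner: reproduce the study's report tables on any cohort.

A plan names subgroups (filters over sex, leukocyte band and disease
history), marker sets, and the methods to run on each combination:
single-marker verification at the fixed cutoffs, OR-combination, overlap
partitioning, specificity-constrained panel optimization and its
cross-validation, and case-vs-control Wilcoxon tests. The output bundle is
a plain nested dict (JSON-serialisable) holding, for every cell, the raw
count ratios alongside display percentages, plus a structured log of every
exclusion (subgroup filters and missing-value unclassifications).

Display rounding is one decimal place, round-half-up; raw ratios are always
retained so nothing is lost to formatting.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, SubgroupFilter, case_control_labels, select_subgroup
from .combine import StatusMatrix, or_combine_matrix, overlap_partition
from .errors import UndefinedMetricError, UropanelError
from .metrics import (
    ClassificationStatus,
    classify_values,
    performance,
    roc_curve,
    wilcoxon_rank_sum,
)
from .panel import OptimizerConfig, cross_validate, optimize_panel

__all__ = [
    "AnalysisSpec",
    "AnalysisPlan",
    "default_plan",
    "run_plan",
    "write_report_bundle",
    "round_half_up",
]

_METHODS = {"single", "or", "overlap", "panel", "cv"}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1 at one digit), as report tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(ratio: float) -> float:
    return round_half_up(100.0 * ratio, 1)


@dataclass(frozen=True)
class AnalysisSpec:
    """One report row group: a subgroup, a marker set, and methods to run."""

    name: str
    subgroup: str
    markers: tuple[str, ...]
    methods: frozenset = frozenset({"single", "or", "overlap"})

    def __post_init__(self) -> None:
        unknown = set(self.methods) - _METHODS
        if unknown:
            raise UropanelError(f"unknown method(s) {sorted(unknown)} in analysis {self.name!r}")


@dataclass(frozen=True)
class AnalysisPlan:
    subgroups: Mapping[str, SubgroupFilter]
    analyses: tuple[AnalysisSpec, ...]
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    cv_k: int = 3
    cv_repeats: int = 10

    def __post_init__(self) -> None:
        for spec in self.analyses:
            if spec.subgroup not in self.subgroups:
                raise UropanelError(
                    f"analysis {spec.name!r} references unknown subgroup {spec.subgroup!r}"
                )


def default_plan(cv_repeats: int = 10) -> AnalysisPlan:
    """The study layout: methylation trio on low-leukocyte men, protein pair
    on the mixed collective, all five markers on four sub-collectives."""
    from .cohort import LeukocyteBand, Sex, UcaHistory

    meth = ("ALOX5", "Chr16", "TRPS1")
    prot = ("CXCL16", "TGFBI")
    allm = meth + prot
    subgroups = {
        "overall": SubgroupFilter(),
        "no_history": SubgroupFilter(uca_history=UcaHistory.NO),
        "male": SubgroupFilter(sex=Sex.MALE),
        "male_no_history": SubgroupFilter(sex=Sex.MALE, uca_history=UcaHistory.NO),
        "male_low_leuk": SubgroupFilter(sex=Sex.MALE, leukocyte_band_below=LeukocyteBand.B500),
        "male_low_leuk_no_history": SubgroupFilter(
            sex=Sex.MALE,
            leukocyte_band_below=LeukocyteBand.B500,
            uca_history=UcaHistory.NO,
        ),
    }
    single = frozenset({"single", "or", "overlap"})
    combo = frozenset({"or", "panel", "cv", "overlap"})
    analyses = (
        AnalysisSpec("methylation_overall", "male_low_leuk", meth, single),
        AnalysisSpec("methylation_no_history", "male_low_leuk_no_history", meth, single),
        AnalysisSpec("protein_overall", "overall", prot, single),
        AnalysisSpec("protein_no_history", "no_history", prot, single),
        AnalysisSpec("all_markers_overall", "overall", allm, combo),
        AnalysisSpec("all_markers_no_history", "no_history", allm, combo),
        AnalysisSpec("all_markers_male", "male", allm, combo),
        AnalysisSpec("all_markers_male_no_history", "male_no_history", allm, combo),
    )
    return AnalysisPlan(subgroups=subgroups, analyses=analyses, cv_repeats=cv_repeats)


def _perf_cell(perf) -> dict:
    return {
        "n_cases_used": perf.n_cases_used,
        "n_controls_used": perf.n_controls_used,
        "n_used": perf.n_used,
        "sensitivity": perf.sensitivity,
        "specificity": perf.specificity,
        "sensitivity_pct": _pct(perf.sensitivity),
        "specificity_pct": _pct(perf.specificity),
    }


def run_plan(table: CohortTable, plan: AnalysisPlan, seed: int = 0) -> dict:
    """Execute a plan and return the report bundle.

    Deterministic given the seed (used only by cross-validation). Undefined
    metrics (an empty classified class) are reported per cell as an
    ``error`` entry, never as silent zeros.
    """
    bundle: dict = {"analyses": {}, "exclusion_log": []}
    log = bundle["exclusion_log"]
    for spec in plan.analyses:
        sub = select_subgroup(table, plan.subgroups[spec.subgroup])
        log.append(
            {
                "analysis": spec.name,
                "step": "subgroup_filter",
                "subgroup": spec.subgroup,
                "n_before": len(table),
                "n_after": len(sub),
                "n_excluded": len(table) - len(sub),
            }
        )
        labels = case_control_labels(sub)
        markers = [sub.marker(m) for m in spec.markers]
        entry: dict = {
            "subgroup": spec.subgroup,
            "markers": list(spec.markers),
            "collective_n": len(sub),
            "n_cases": int(labels.sum()),
            "n_controls": int((~labels).sum()),
        }
        matrix = StatusMatrix.from_cohort(sub, markers)

        if "single" in spec.methods:
            entry["single_markers"] = {}
            for j, marker in enumerate(markers):
                values = [s.values.get(marker.name) for s in sub.subjects]
                statuses = classify_values(values, marker)
                cell: dict = {"threshold": marker.threshold}
                try:
                    cell.update(_perf_cell(performance(statuses, labels)))
                except UndefinedMetricError as exc:
                    cell["error"] = str(exc)
                try:
                    cell["auc"] = roc_curve(values, labels).auc
                except UndefinedMetricError as exc:
                    cell["auc_error"] = str(exc)
                x = [v for v, c in zip(values, labels) if c and v is not None]
                y = [v for v, c in zip(values, labels) if not c and v is not None]
                if x and y:
                    stat, p = wilcoxon_rank_sum(x, y)
                    cell["wilcoxon_p"] = p
                entry["single_markers"][marker.name] = cell
                n_missing = sum(
                    1 for s in statuses if s is ClassificationStatus.UNCLASSIFIED
                )
                log.append(
                    {
                        "analysis": spec.name,
                        "step": "missing_marker_values",
                        "marker": marker.name,
                        "n_excluded": n_missing,
                    }
                )

        if "or" in spec.methods:
            combined = or_combine_matrix(matrix)
            cell = {}
            try:
                cell.update(_perf_cell(performance(combined, labels)))
            except UndefinedMetricError as exc:
                cell["error"] = str(exc)
            n_uncl = sum(1 for s in combined if s is ClassificationStatus.UNCLASSIFIED)
            cell["n_unclassified"] = n_uncl
            entry["or_combination"] = cell
            log.append(
                {
                    "analysis": spec.name,
                    "step": "or_unclassified",
                    "n_excluded": n_uncl,
                }
            )

        if "overlap" in spec.methods:
            part = overlap_partition(matrix)
            entry["overlap"] = {
                "n_complete": part.n_complete,
                "n_excluded": part.n_excluded,
                "cells": [
                    {"subset": sorted(k), "count": v} for k, v in sorted(
                        part.counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                    )
                ],
            }
            log.append(
                {
                    "analysis": spec.name,
                    "step": "overlap_complete_case",
                    "n_excluded": part.n_excluded,
                }
            )

        if "panel" in spec.methods:
            try:
                panel = optimize_panel(sub, spec.markers, plan.optimizer)
                entry["panel"] = {
                    "markers": list(panel.markers),
                    "thresholds": list(panel.thresholds),
                    "score_threshold": panel.score_threshold,
                    "feasible": panel.feasible,
                    **_perf_cell(panel.training_performance),
                }
            except UropanelError as exc:
                entry["panel"] = {"error": str(exc)}

        if "cv" in spec.methods:
            try:
                cv = cross_validate(
                    sub,
                    spec.markers,
                    plan.optimizer,
                    k=plan.cv_k,
                    repeats=plan.cv_repeats,
                    seed=seed,
                )
                entry["cv"] = {
                    "k": cv.k,
                    "repeats": cv.repeats,
                    "mean_sensitivity": cv.mean_sensitivity,
                    "mean_specificity": cv.mean_specificity,
                    "mean_sensitivity_pct": _pct(cv.mean_sensitivity),
                    "mean_specificity_pct": _pct(cv.mean_specificity),
                    "repeat_means": [
                        {"sensitivity": s, "specificity": p} for s, p in cv.repeat_means
                    ],
                    "folds": [
                        {
                            "repeat": f.repeat,
                            "fold": f.fold,
                            "markers": list(f.panel.markers),
                            "score_threshold": f.panel.score_threshold,
                            "test_sensitivity": f.test_performance.sensitivity,
                            "test_specificity": f.test_performance.specificity,
                        }
                        for f in cv.folds
                    ],
                }
            except UropanelError as exc:
                entry["cv"] = {"error": str(exc)}

        bundle["analyses"][spec.name] = entry
    return bundle


def write_report_bundle(bundle: dict, outdir: str | Path) -> None:
    """Write the bundle as JSON plus tidy CSV extracts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)

    single_rows, combo_rows, overlap_rows = [], [], []
    for name, entry in bundle["analyses"].items():
        for marker, cell in entry.get("single_markers", {}).items():
            single_rows.append({"analysis": name, "marker": marker, **_flat(cell)})
        for method in ("or_combination", "panel", "cv"):
            if method in entry:
                combo_rows.append({"analysis": name, "method": method, **_flat(entry[method])})
        if "overlap" in entry:
            for cell in entry["overlap"]["cells"]:
                overlap_rows.append(
                    {
                        "analysis": name,
                        "subset": "+".join(cell["subset"]) or "(none)",
                        "count": cell["count"],
                    }
                )
    if single_rows:
        pd.DataFrame(single_rows).to_csv(outdir / "single_markers.csv", index=False)
    if combo_rows:
        pd.DataFrame(combo_rows).to_csv(outdir / "combinations.csv", index=False)
    if overlap_rows:
        pd.DataFrame(overlap_rows).to_csv(outdir / "overlap.csv", index=False)
    pd.DataFrame(bundle["exclusion_log"]).to_csv(outdir / "exclusion_log.csv", index=False)


def _flat(cell: Mapping) -> dict:
    return {k: v for k, v in cell.items() if not isinstance(v, (list, dict))}
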