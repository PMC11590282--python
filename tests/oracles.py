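"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (plain Python loops over every subject and
every panel) and share no code with the package's optimizer, so they can
serve as an oracle for it.
"""
from __future__ import annotations

import itertools
import math


def naive_candidates(values, labels):
    """Class-change gap midpoints, re-derived with plain loops."""
    pairs = sorted(
        (v, l) for v, l in zip(values, labels) if v is not None and not math.isnan(v)
    )
    comp = {}
    for v, l in pairs:
        comp.setdefault(v, set()).add(l)
    distinct = sorted(comp)
    mids = []
    for a, b in zip(distinct, distinct[1:]):
        if comp[a] != comp[b]:
            mids.append((a + b) / 2.0)
    return mids


def naive_panel_performance(rows, labels, subset, thresholds, s):
    """rows: list of dicts marker -> value (complete cases only)."""
    tp = fn = tn = fp = 0
    for row, is_case in zip(rows, labels):
        score = sum(1 for m, t in zip(subset, thresholds) if row[m] >= t)
        pos = score >= s
        if is_case:
            tp += pos
            fn += not pos
        else:
            fp += pos
            tn += not pos
    return tp / (tp + fn), tn / (tn + fp)


def brute_force_optimize(rows, labels, marker_names, min_specificity, max_panel_size):
    """Triple-loop exhaustive panel search with the documented tie-breaks.

    Returns (markers, thresholds, s, sensitivity, specificity, feasible).
    """
    names = sorted(marker_names)
    cands = {}
    for m in names:
        c = naive_candidates([r[m] for r in rows], labels)
        if c:
            cands[m] = c
    usable = [m for m in names if m in cands]
    if not usable:
        return None  # degenerate instance: no marker separates anything
    feasible_best = None
    fallback_best = None
    for size in range(1, min(max_panel_size, len(usable)) + 1):
        for subset in itertools.combinations(usable, size):
            for thresholds in itertools.product(*(cands[m] for m in subset)):
                for s in range(1, size + 1):
                    sens, spec = naive_panel_performance(rows, labels, subset, thresholds, s)
                    rec = (subset, thresholds, s, sens, spec)
                    fkey = (-sens, -spec, size, s, subset, thresholds)
                    akey = (-spec, -sens, size, s, subset, thresholds)
                    if spec >= min_specificity and (
                        feasible_best is None or fkey < feasible_best[0]
                    ):
                        feasible_best = (fkey, rec)
                    if fallback_best is None or akey < fallback_best[0]:
                        fallback_best = (akey, rec)
    if feasible_best is not None:
        subset, thresholds, s, sens, spec = feasible_best[1]
        return subset, thresholds, s, sens, spec, True
    subset, thresholds, s, sens, spec = fallback_best[1]
    return subset, thresholds, s, sens, spec, False
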