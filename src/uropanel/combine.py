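"""Boolean OR-combination of marker calls and exact overlap partitioning.

The OR rule declares a subject positive as soon as *any* marker in the set
meets its cutoff — even when other markers are missing, since one exceeded
threshold is decisive on its own. A subject is negative only when every
marker is present and negative. When at least one marker is missing and the
remaining markers are all negative, the subject is left unclassified: the
missing marker could have been the positive one.

Overlap partitioning (the counts behind a Venn diagram) is complete-case by
construction: a subject with any unclassified marker is excluded and tallied
separately, and each remaining subject falls into exactly one cell — the
subset of markers for which it is positive (the empty set is the
all-negative cell).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, MarkerDefinition
from .errors import UropanelError
from .metrics import ClassificationStatus, classify_marker

__all__ = ["StatusMatrix", "OverlapPartition", "or_combine", "or_combine_matrix", "overlap_partition"]

_CODE = {
    ClassificationStatus.NEGATIVE: 0,
    ClassificationStatus.POSITIVE: 1,
    ClassificationStatus.UNCLASSIFIED: -1,
}
_STATUS = {v: k for k, v in _CODE.items()}


@dataclass(frozen=True)
class StatusMatrix:
    """Subjects x markers grid of classification statuses.

    Stored as an int8 array (1 positive, 0 negative, -1 unclassified) with
    the marker order recorded.
    """

    marker_names: tuple[str, ...]
    codes: np.ndarray  # shape (n_subjects, n_markers), int8
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.marker_names):
            raise UropanelError("status matrix must be rectangular with one column per marker")
        if self.subject_ids and len(self.subject_ids) != self.codes.shape[0]:
            raise UropanelError("subject_ids must align with status rows")

    @classmethod
    def from_cohort(
        cls, table: CohortTable, markers: Sequence[MarkerDefinition] | None = None
    ) -> "StatusMatrix":
        markers = list(markers) if markers is not None else list(table.markers)
        codes = np.empty((len(table.subjects), len(markers)), dtype=np.int8)
        for i, subj in enumerate(table.subjects):
            for j, m in enumerate(markers):
                codes[i, j] = _CODE[classify_marker(subj.values.get(m.name), m)]
        return cls(
            marker_names=tuple(m.name for m in markers),
            codes=codes,
            subject_ids=tuple(s.subject_id for s in table.subjects),
        )

    def row(self, i: int) -> list[ClassificationStatus]:
        return [_STATUS[int(c)] for c in self.codes[i]]

    def __len__(self) -> int:
        return self.codes.shape[0]


def or_combine(statuses: Iterable[ClassificationStatus]) -> ClassificationStatus:
    """OR rule for one subject's marker statuses.

    Positive if any marker is positive; negative if all are negative;
    unclassified if no marker is positive and at least one is missing.
    """
    statuses = list(statuses)
    if not statuses:
        raise UropanelError("or_combine requires at least one marker status")
    if any(s is ClassificationStatus.POSITIVE for s in statuses):
        return ClassificationStatus.POSITIVE
    if any(s is ClassificationStatus.UNCLASSIFIED for s in statuses):
        return ClassificationStatus.UNCLASSIFIED
    return ClassificationStatus.NEGATIVE


def or_combine_matrix(matrix: StatusMatrix) -> list[ClassificationStatus]:
    """Vectorised OR rule over every subject row of a status matrix."""
    codes = matrix.codes
    any_pos = (codes == 1).any(axis=1)
    any_missing = (codes == -1).any(axis=1)
    out = []
    for pos, miss in zip(any_pos, any_missing):
        if pos:
            out.append(ClassificationStatus.POSITIVE)
        elif miss:
            out.append(ClassificationStatus.UNCLASSIFIED)
        else:
            out.append(ClassificationStatus.NEGATIVE)
    return out


@dataclass(frozen=True)
class OverlapPartition:
    """Counts of subjects per positive-marker subset among complete cases.

    ``counts`` maps each subset of the marker set (as a frozenset of names;
    the empty set is the all-negative cell) to a subject count; cells sum to
    ``n_complete``. Subjects with any unclassified marker are excluded and
    counted in ``n_excluded``.
    """

    marker_names: tuple[str, ...]
    counts: Mapping[frozenset, int]
    n_excluded: int

    @property
    def n_complete(self) -> int:
        return sum(self.counts.values())

    def positive_count(self, marker: str) -> int:
        """Complete-case positives for one marker (sum of cells containing it)."""
        if marker not in self.marker_names:
            raise UropanelError(f"unknown marker {marker!r}")
        return sum(c for subset, c in self.counts.items() if marker in subset)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per subset with a bitmask in marker order."""
        rows = []
        for subset, count in sorted(self.counts.items(), key=lambda kv: sorted(kv[0])):
            mask = "".join("1" if m in subset else "0" for m in self.marker_names)
            rows.append(
                {"subset": "+".join(sorted(subset)) or "(none)", "bitmask": mask, "count": count}
            )
        return pd.DataFrame(rows, columns=["subset", "bitmask", "count"])


def overlap_partition(matrix: StatusMatrix) -> OverlapPartition:
    """Partition complete-case subjects by their set of positive markers."""
    counts: dict[frozenset, int] = {}
    excluded = 0
    names = matrix.marker_names
    for row in matrix.codes:
        if (row == -1).any():
            excluded += 1
            continue
        subset = frozenset(names[j] for j in np.flatnonzero(row == 1))
        counts[subset] = counts.get(subset, 0) + 1
    return OverlapPartition(marker_names=names, counts=counts, n_excluded=excluded)
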