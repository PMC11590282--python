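import numpy as np
import pytest

from uropanel.cohort import (
    CohortTable,
    Group,
    MarkerDefinition,
    MarkerLevel,
    SubjectRecord,
)


def make_cohort(markers, rows):
    """Build a cohort from (group, {marker: value}) or
    (group, {marker: value}, extra-kwargs) tuples."""
    subjects = []
    for i, row in enumerate(rows):
        group, values, *rest = row
        kwargs = rest[0] if rest else {}
        subjects.append(
            SubjectRecord(subject_id=f"s{i}", group=Group(group), values=dict(values), **kwargs)
        )
    return CohortTable(markers=list(markers), subjects=subjects)


@pytest.fixture
def two_proteins():
    return [
        MarkerDefinition("A", MarkerLevel.PROTEIN, 10.0),
        MarkerDefinition("B", MarkerLevel.PROTEIN, 20.0),
    ]


def random_integer_cohort(rng, n_markers=3, n_subjects=30, support=6):
    """Small cohort with heavily tied integer marker values, for oracle tests."""
    names = [f"M{j}" for j in range(n_markers)]
    markers = [MarkerDefinition(n, MarkerLevel.PROTEIN, 1.0) for n in names]
    rows = []
    labels = rng.random(n_subjects) < 0.4
    # guarantee at least two complete cases and controls
    labels[:2] = True
    labels[2:4] = False
    for i in range(n_subjects):
        shift = rng.integers(0, 3) if labels[i] else 0
        values = {n: float(rng.integers(0, support) + shift) for n in names}
        rows.append(("uca" if labels[i] else "no_cancer", values))
    return make_cohort(markers, rows), names
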