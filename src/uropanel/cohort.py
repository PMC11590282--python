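"""Cohort domain model, CSV input/output, and subgroup selection.

A cohort is a flat table of study participants. Each participant carries a
diagnostic group (urothelial carcinoma, another genitourinary/gynecologic
cancer, or no cancer), a handful of clinical covariates recorded as
categorical bands (urine stick tests report leukocytes and erythrocytes in
coarse bands, not continuous counts), and one value per declared biomarker.
Biomarker values may be absent; absence is modelled as a distinct state
(``None`` in memory, an empty cell or ``NA`` on disk), never as a sentinel
number, because missingness drives the downstream classification contract.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CohortFormatError, CohortValidationError, ConfigurationError

__all__ = [
    "Group",
    "Sex",
    "AgeBand",
    "LeukocyteBand",
    "ErythrocyteBand",
    "UcaHistory",
    "Grade",
    "MarkerLevel",
    "MarkerDefinition",
    "SubjectRecord",
    "CohortTable",
    "SubgroupFilter",
    "DEFAULT_MARKERS",
    "read_cohort",
    "write_cohort",
    "load_marker_spec",
    "select_subgroup",
    "case_control_labels",
]


class Group(str, Enum):
    UCA = "uca"
    OTHER_CANCER = "other_cancer"
    NO_CANCER = "no_cancer"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class AgeBand(str, Enum):
    LT70 = "lt70"
    GE70 = "ge70"
    UNKNOWN = "unknown"


class LeukocyteBand(str, Enum):
    """Urine-stick leukocyte band (~cells/uL); ordinal, 'neg' lowest."""

    NEG = "neg"
    B10 = "b10"
    B25 = "b25"
    B100 = "b100"
    B500 = "b500"
    UNKNOWN = "unknown"


class ErythrocyteBand(str, Enum):
    """Urine-stick erythrocyte band (~cells/uL); ordinal, 'neg' lowest."""

    NEG = "neg"
    B10 = "b10"
    B25 = "b25"
    B50 = "b50"
    B250 = "b250"
    UNKNOWN = "unknown"


class UcaHistory(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Grade(str, Enum):
    LOW = "low"
    HIGH = "high"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"


class MarkerLevel(str, Enum):
    METHYLATION = "methylation"
    PROTEIN = "protein"


#: Ordinal positions for band comparisons; 'unknown' deliberately has no rank.
_LEUKOCYTE_ORDER = {
    LeukocyteBand.NEG: 0,
    LeukocyteBand.B10: 1,
    LeukocyteBand.B25: 2,
    LeukocyteBand.B100: 3,
    LeukocyteBand.B500: 4,
}

_UNITS_BY_LEVEL = {
    MarkerLevel.METHYLATION: "fraction_0_1",
    MarkerLevel.PROTEIN: "pg_per_mg_creatinine",
}


@dataclass(frozen=True)
class MarkerDefinition:
    """A biomarker with its positivity cutoff.

    Positivity is always "value >= threshold" (both the methylation fractions
    and the creatinine-normalised protein concentrations rise in disease).
    Methylation thresholds are fractions in [0, 1]; protein thresholds are
    concentrations in pg per mg creatinine.
    """

    name: str
    level: MarkerLevel
    threshold: float
    units: str = ""
    direction: str = "higher_is_positive"

    def __post_init__(self) -> None:
        level = MarkerLevel(self.level)
        object.__setattr__(self, "level", level)
        units = self.units or _UNITS_BY_LEVEL[level]
        if units != _UNITS_BY_LEVEL[level]:
            raise ConfigurationError(
                f"marker {self.name!r}: units {units!r} incompatible with level {level.value!r}"
            )
        object.__setattr__(self, "units", units)
        if self.direction != "higher_is_positive":
            raise ConfigurationError(
                f"marker {self.name!r}: only 'higher_is_positive' markers are supported"
            )
        if not math.isfinite(self.threshold) or self.threshold < 0:
            raise ConfigurationError(
                f"marker {self.name!r}: threshold must be a finite non-negative number"
            )
        if level is MarkerLevel.METHYLATION and not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(
                f"marker {self.name!r}: methylation threshold {self.threshold} outside [0, 1]"
            )


#: The five study markers with the cutoffs fixed in the identification studies
#: (methylation fractions; proteins in pg/mg creatinine).
DEFAULT_MARKERS: tuple[MarkerDefinition, ...] = (
    MarkerDefinition("ALOX5", MarkerLevel.METHYLATION, 0.435),
    MarkerDefinition("TRPS1", MarkerLevel.METHYLATION, 0.465),
    MarkerDefinition("Chr16", MarkerLevel.METHYLATION, 0.555),
    MarkerDefinition("CXCL16", MarkerLevel.PROTEIN, 648.52),
    MarkerDefinition("TGFBI", MarkerLevel.PROTEIN, 1345.97),
)


@dataclass
class SubjectRecord:
    """One study participant with covariates and (possibly missing) marker values."""

    subject_id: str
    group: Group
    sex: Sex = Sex.UNKNOWN
    age_band: AgeBand = AgeBand.UNKNOWN
    leukocyte_band: LeukocyteBand = LeukocyteBand.UNKNOWN
    erythrocyte_band: ErythrocyteBand = ErythrocyteBand.UNKNOWN
    uca_history: UcaHistory = UcaHistory.UNKNOWN
    grade: Grade = Grade.NOT_APPLICABLE
    values: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.sex = Sex(self.sex)
        self.age_band = AgeBand(self.age_band)
        self.leukocyte_band = LeukocyteBand(self.leukocyte_band)
        self.erythrocyte_band = ErythrocyteBand(self.erythrocyte_band)
        self.uca_history = UcaHistory(self.uca_history)
        self.grade = Grade(self.grade)
        if self.group is not Group.UCA and self.grade not in (Grade.NOT_APPLICABLE,):
            raise CohortValidationError(
                f"subject {self.subject_id!r}: tumor grade only applies to the UCa group"
            )


@dataclass
class CohortTable:
    """A validated cohort: declared markers plus one record per subject."""

    markers: list[MarkerDefinition]
    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate marker names in cohort definition")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate subject_id values in cohort")
        by_name = {m.name: m for m in self.markers}
        for subj in self.subjects:
            for key, value in subj.values.items():
                marker = by_name.get(key)
                if marker is None:
                    raise CohortValidationError(
                        f"subject {subj.subject_id!r}: value for undeclared marker {key!r}"
                    )
                if value is None:
                    continue
                if not math.isfinite(value) or value < 0:
                    raise CohortValidationError(
                        f"subject {subj.subject_id!r}: marker {key!r} value {value!r} "
                        "must be finite and non-negative"
                    )
                if marker.level is MarkerLevel.METHYLATION and not 0.0 <= value <= 1.0:
                    raise CohortValidationError(
                        f"subject {subj.subject_id!r}: methylation fraction {value} for "
                        f"{key!r} outside [0, 1]"
                    )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker(self, name: str) -> MarkerDefinition:
        for m in self.markers:
            if m.name == name:
                return m
        raise ConfigurationError(f"unknown marker {name!r}")

    def values_matrix(self, marker_names: Sequence[str] | None = None) -> np.ndarray:
        """Subjects x markers float array; missing values become NaN."""
        names = list(marker_names) if marker_names is not None else self.marker_names
        for n in names:
            self.marker(n)  # raises on unknown
        out = np.full((len(self.subjects), len(names)), np.nan)
        for i, subj in enumerate(self.subjects):
            for j, n in enumerate(names):
                v = subj.values.get(n)
                if v is not None:
                    out[i, j] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row: dict[str, object] = {
                "subject_id": s.subject_id,
                "group": s.group.value,
                "sex": s.sex.value,
                "age_band": s.age_band.value,
                "leukocyte_band": s.leukocyte_band.value,
                "erythrocyte_band": s.erythrocyte_band.value,
                "uca_history": s.uca_history.value,
                "grade": s.grade.value,
            }
            for m in self.markers:
                row[m.name] = s.values.get(m.name)
            rows.append(row)
        columns = _COVARIATE_COLUMNS + self.marker_names
        return pd.DataFrame(rows, columns=columns)


_COVARIATE_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age_band",
    "leukocyte_band",
    "erythrocyte_band",
    "uca_history",
    "grade",
]

#: On-disk tokens that denote an absent marker value.
_MISSING_TOKENS = {"", "NA"}


def _parse_enum(enum_cls, raw: str, column: str, subject_id: str):
    try:
        return enum_cls(raw)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise CohortValidationError(
            f"subject {subject_id!r}: {column}={raw!r} is not one of ({allowed})"
        ) from None


def read_cohort(path: str | Path, markers: Sequence[MarkerDefinition] = DEFAULT_MARKERS) -> CohortTable:
    """Read a cohort CSV and validate it against a marker specification.

    The file is comma-separated UTF-8 with a header row; marker columns are
    named exactly after the markers and hold decimal numbers, with an empty
    cell or ``NA`` meaning "not measured". Out-of-range methylation fractions
    and unrecognised categorical labels raise, they are never coerced.
    """
    markers = list(markers)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = _COVARIATE_COLUMNS + [m.name for m in markers]
    for col in required:
        if col not in df.columns:
            raise CohortFormatError(f"cohort file {path} is missing required column {col!r}")
    subjects = []
    for _, raw in df.iterrows():
        sid = raw["subject_id"]
        values: dict[str, float | None] = {}
        for m in markers:
            token = raw[m.name].strip()
            if token in _MISSING_TOKENS:
                values[m.name] = None
            else:
                try:
                    values[m.name] = float(token)
                except ValueError:
                    raise CohortValidationError(
                        f"subject {sid!r}: marker {m.name!r} value {token!r} is not numeric"
                    ) from None
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=_parse_enum(Group, raw["group"], "group", sid),
                sex=_parse_enum(Sex, raw["sex"], "sex", sid),
                age_band=_parse_enum(AgeBand, raw["age_band"], "age_band", sid),
                leukocyte_band=_parse_enum(LeukocyteBand, raw["leukocyte_band"], "leukocyte_band", sid),
                erythrocyte_band=_parse_enum(
                    ErythrocyteBand, raw["erythrocyte_band"], "erythrocyte_band", sid
                ),
                uca_history=_parse_enum(UcaHistory, raw["uca_history"], "uca_history", sid),
                grade=_parse_enum(Grade, raw["grade"], "grade", sid),
                values=values,
            )
        )
    return CohortTable(markers=markers, subjects=subjects)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort as CSV (missing marker values become empty cells)."""
    df = table.to_frame()
    df.to_csv(path, index=False, na_rep="")


def load_marker_spec(path: str | Path) -> list[MarkerDefinition]:
    """Load marker definitions from a YAML/JSON list of mappings."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigurationError("marker spec must be a list of marker mappings")
    out = []
    for entry in raw:
        try:
            out.append(
                MarkerDefinition(
                    name=entry["name"],
                    level=MarkerLevel(entry["level"]),
                    threshold=float(entry["threshold"]),
                    units=entry.get("units", ""),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid marker spec entry {entry!r}: {exc}") from exc
    return out


@dataclass(frozen=True)
class SubgroupFilter:
    """Conjunction of covariate clauses used to carve out analysis subgroups.

    ``leukocyte_band_below`` keeps subjects whose leukocyte band is strictly
    below the given band (the stick test reports bands, so "< 500 cells/uL"
    means every band below the ~500 band). Subjects whose value for a
    filtered covariate is unknown are excluded, mirroring how tables report
    "unknown" rows separately rather than folding them into a stratum.
    """

    sex: Sex | None = None
    leukocyte_band_below: LeukocyteBand | None = None
    uca_history: UcaHistory | None = None

    def __post_init__(self) -> None:
        if self.sex is not None and Sex(self.sex) is Sex.UNKNOWN:
            raise ConfigurationError("cannot filter on sex='unknown'")
        if self.uca_history is not None and UcaHistory(self.uca_history) is UcaHistory.UNKNOWN:
            raise ConfigurationError("cannot filter on uca_history='unknown'")
        if self.leukocyte_band_below is not None:
            band = LeukocyteBand(self.leukocyte_band_below)
            if band not in _LEUKOCYTE_ORDER:
                raise ConfigurationError("leukocyte_band_below must be an ordered band")

    def matches(self, subject: SubjectRecord) -> bool:
        if self.sex is not None and subject.sex is not Sex(self.sex):
            return False
        if self.uca_history is not None and subject.uca_history is not UcaHistory(self.uca_history):
            return False
        if self.leukocyte_band_below is not None:
            rank = _LEUKOCYTE_ORDER.get(subject.leukocyte_band)
            if rank is None or rank >= _LEUKOCYTE_ORDER[LeukocyteBand(self.leukocyte_band_below)]:
                return False
        return True

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SubgroupFilter":
        allowed = {"sex", "leukocyte_band_below", "uca_history"}
        unknown = set(mapping) - allowed
        if unknown:
            raise ConfigurationError(f"unknown subgroup filter field(s): {sorted(unknown)}")
        kwargs: dict[str, object] = {}
        if "sex" in mapping:
            kwargs["sex"] = Sex(mapping["sex"])
        if "leukocyte_band_below" in mapping:
            kwargs["leukocyte_band_below"] = LeukocyteBand(mapping["leukocyte_band_below"])
        if "uca_history" in mapping:
            kwargs["uca_history"] = UcaHistory(mapping["uca_history"])
        return cls(**kwargs)


def select_subgroup(table: CohortTable, subgroup: SubgroupFilter) -> CohortTable:
    """Return the sub-cohort satisfying every clause of the filter."""
    kept = [s for s in table.subjects if subgroup.matches(s)]
    return CohortTable(markers=list(table.markers), subjects=kept)


def case_control_labels(table: CohortTable) -> np.ndarray:
    """Boolean case labels: UCa is the case class; every other group -
    other cancers included - is control."""
    return np.array([s.group is Group.UCA for s in table.subjects], dtype=bool)
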