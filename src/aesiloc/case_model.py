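"""Domain types for AESI surveillance line lists.

A *case* is one suspected adverse event of special interest (AESI) in a
hospital roster: a condition code, demographics, the detection site, and a
tri-state (present / absent / unknown) assignment for each case-definition
criterion.  Unrecorded criteria always read as UNKNOWN — a blank cell is an
undocumented test, never a negative finding.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "TriValue",
    "ConditionCode",
    "Sex",
    "Residence",
    "DetectionSite",
    "CriterionCategory",
    "CriterionDef",
    "Atom",
    "AllOf",
    "AnyOf",
    "AtLeast",
    "Not",
    "RuleExpr",
    "RuleSet",
    "CaseRecord",
    "LOCResult",
    "LineListError",
    "tri_from_token",
    "tri_to_token",
    "expr_atoms",
    "read_line_list",
    "write_line_list",
    "CRITERION_COLUMN_PREFIX",
    "FIXED_COLUMNS",
]

CRITERION_COLUMN_PREFIX = "crit."
FIXED_COLUMNS = ("case_id", "condition", "age", "sex", "residence", "detection_site")

#: Nadir window (hours) for the GBS temporal criterion: 12 h to 28 days.
GBS_NADIR_WINDOW_HOURS = (12.0, 28 * 24.0)
GBS_TEMPORAL_CRITERION = "onset_nadir_12h_28d"


class LineListError(ValueError):
    """Raised on malformed line-list content; message names row and column."""


class TriValue(enum.Enum):
    """Tri-state value of one case-definition criterion."""

    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    UNKNOWN = "UNKNOWN"


_TOKEN_MAP = {
    "yes": TriValue.PRESENT,
    "y": TriValue.PRESENT,
    "1": TriValue.PRESENT,
    "no": TriValue.ABSENT,
    "n": TriValue.ABSENT,
    "0": TriValue.ABSENT,
    "": TriValue.UNKNOWN,
    "unknown": TriValue.UNKNOWN,
    "na": TriValue.UNKNOWN,
}

_TRI_TO_TOKEN = {TriValue.PRESENT: "yes", TriValue.ABSENT: "no", TriValue.UNKNOWN: ""}


def tri_from_token(token: str, *, row: object = "?", column: object = "?") -> TriValue:
    """Parse a line-list cell into a :class:`TriValue`.

    ``yes``/``y``/``1`` map to PRESENT, ``no``/``n``/``0`` to ABSENT, and
    blank/``unknown``/``na`` to UNKNOWN (case-insensitive).  Anything else is
    a :class:`LineListError` naming the offending row and column.
    """
    key = token.strip().lower()
    try:
        return _TOKEN_MAP[key]
    except KeyError:
        raise LineListError(
            f"unrecognized tri-state token {token!r} at row {row}, column {column!r}"
        ) from None


def tri_to_token(value: TriValue) -> str:
    return _TRI_TO_TOKEN[value]


class ConditionCode(enum.Enum):
    """Closed vocabulary of surveillance conditions.

    ENCEPHALITIS and MYELITIS are distinct codes; a dual-diagnosed patient is
    represented as two case records.
    """

    MYOCARDITIS = "MYOCARDITIS"
    PERICARDITIS = "PERICARDITIS"
    INJECTION_SITE_ABSCESS = "INJECTION_SITE_ABSCESS"
    TTS = "TTS"
    THROMBOCYTOPENIA = "THROMBOCYTOPENIA"
    THROMBOSIS_THROMBOEMBOLISM = "THROMBOSIS_THROMBOEMBOLISM"
    ANAPHYLAXIS = "ANAPHYLAXIS"
    ADEM = "ADEM"
    BELLS_PALSY = "BELLS_PALSY"
    GENERALIZED_CONVULSION = "GENERALIZED_CONVULSION"
    GBS_FISHER = "GBS_FISHER"
    ENCEPHALITIS = "ENCEPHALITIS"
    MYELITIS = "MYELITIS"


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class Residence(enum.Enum):
    ADDIS_ABABA = "ADDIS_ABABA"
    OUTSIDE = "OUTSIDE"


class DetectionSite(enum.Enum):
    EOPD = "EOPD"  # emergency outpatient department
    IPD = "IPD"  # inpatient department


class CriterionCategory(enum.Enum):
    CLINICAL = "CLINICAL"
    TEMPORAL = "TEMPORAL"
    LABORATORY = "LABORATORY"
    ELECTROPHYSIOLOGY = "ELECTROPHYSIOLOGY"
    IMAGING = "IMAGING"
    EXCLUSION = "EXCLUSION"


@dataclass(frozen=True)
class CriterionDef:
    """One case-definition criterion: id, display label, grouping category."""

    id: str
    label: str
    category: CriterionCategory


# ---------------------------------------------------------------------------
# Rule expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    criterion: str


@dataclass(frozen=True)
class AllOf:
    children: tuple["RuleExpr", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("ALL requires at least one child")


@dataclass(frozen=True)
class AnyOf:
    children: tuple["RuleExpr", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("ANY requires at least one child")


@dataclass(frozen=True)
class AtLeast:
    k: int
    children: tuple["RuleExpr", ...]

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.children):
            raise ValueError(
                f"AT_LEAST threshold {self.k} out of range for {len(self.children)} children"
            )


@dataclass(frozen=True)
class Not:
    child: "RuleExpr"


RuleExpr = Union[Atom, AllOf, AnyOf, AtLeast, Not]


def expr_atoms(expr: RuleExpr) -> frozenset[str]:
    """All criterion ids referenced anywhere in ``expr``."""
    if isinstance(expr, Atom):
        return frozenset((expr.criterion,))
    if isinstance(expr, Not):
        return expr_atoms(expr.child)
    out: set[str] = set()
    for child in expr.children:
        out |= expr_atoms(child)
    return frozenset(out)


@dataclass(frozen=True)
class RuleSet:
    """Machine form of one condition's case definition.

    ``level1`` is the most specific predicate, ``level3`` the most sensitive.
    Under fully-known assignments, level1 must imply level2 and level2 must
    imply level3; :func:`aesiloc.definitions.validate_rule_set` checks this
    exhaustively.
    """

    condition: ConditionCode
    criteria: tuple[CriterionDef, ...]
    level1: RuleExpr
    level2: RuleExpr
    level3: RuleExpr
    version: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate criterion ids: {dupes}")
        declared = set(ids)
        for level, expr in (1, self.level1), (2, self.level2), (3, self.level3):
            dangling = expr_atoms(expr) - declared
            if dangling:
                raise ValueError(
                    f"level {level} references undeclared criteria: {sorted(dangling)}"
                )

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def level(self, k: int) -> RuleExpr:
        return {1: self.level1, 2: self.level2, 3: self.level3}[k]

    def criterion(self, criterion_id: str) -> CriterionDef:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)


# ---------------------------------------------------------------------------
# Case records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseRecord:
    """One suspected AESI case.

    ``criteria`` is canonicalised on construction: UNKNOWN entries are
    dropped, so an absent key and an explicit UNKNOWN are the same state and
    CSV round-trips compare equal.  ``onset_to_nadir_hours`` is a convenience
    field for GBS; when set it derives the temporal criterion unless that
    criterion was assigned explicitly.
    """

    case_id: str
    condition: ConditionCode
    age: int
    sex: Sex
    residence: Residence
    detection_site: DetectionSite
    criteria: Mapping[str, TriValue] = field(default_factory=dict)
    onset_to_nadir_hours: float | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.onset_to_nadir_hours is not None and self.onset_to_nadir_hours < 0:
            raise ValueError("onset_to_nadir_hours must be non-negative")
        crit = {k: v for k, v in self.criteria.items() if v is not TriValue.UNKNOWN}
        if (
            self.condition is ConditionCode.GBS_FISHER
            and self.onset_to_nadir_hours is not None
            and GBS_TEMPORAL_CRITERION not in crit
        ):
            lo, hi = GBS_NADIR_WINDOW_HOURS
            within = lo <= self.onset_to_nadir_hours <= hi
            crit[GBS_TEMPORAL_CRITERION] = (
                TriValue.PRESENT if within else TriValue.ABSENT
            )
        object.__setattr__(self, "criteria", dict(crit))

    def criterion(self, criterion_id: str) -> TriValue:
        return self.criteria.get(criterion_id, TriValue.UNKNOWN)

    def with_criterion(self, criterion_id: str, value: TriValue) -> "CaseRecord":
        crit = dict(self.criteria)
        crit[criterion_id] = value
        if value is TriValue.UNKNOWN:
            crit.pop(criterion_id, None)
        return replace(self, criteria=crit)


@dataclass(frozen=True)
class LOCResult:
    """Assigned level of certainty with provenance.

    level 4 ⇔ ``blocking_unknowns`` non-empty; level 5 ⇔ ``failed_criteria``
    non-empty.
    """

    level: int
    satisfied_level: int | None = None
    blocking_unknowns: frozenset[str] = frozenset()
    failed_criteria: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4, 5):
            raise ValueError(f"level must be in 1..5, got {self.level}")
        if (self.level == 4) != bool(self.blocking_unknowns):
            raise ValueError("blocking_unknowns must be non-empty iff level == 4")
        if (self.level == 5) != bool(self.failed_criteria):
            raise ValueError("failed_criteria must be non-empty iff level == 5")
        if (self.level in (1, 2, 3)) != (self.satisfied_level is not None):
            raise ValueError("satisfied_level set iff level in 1..3")


# ---------------------------------------------------------------------------
# Line-list CSV I/O
# ---------------------------------------------------------------------------


def _parse_enum(cls, token: str, *, row: int, column: str):
    try:
        return cls(token.strip().upper())
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise LineListError(
            f"row {row}, column {column!r}: {token!r} is not one of {{{valid}}}"
        ) from None


def read_line_list(path: str | Path) -> list[CaseRecord]:
    """Read a line-list CSV into case records.

    Expected header: the fixed columns ``case_id, condition, age, sex,
    residence, detection_site`` followed by one ``crit.<id>`` column per
    criterion.  Unlisted criteria read as UNKNOWN.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in FIXED_COLUMNS if c not in header]
        if missing:
            raise LineListError(f"missing required columns: {missing}")
        crit_columns = [c for c in header if c.startswith(CRITERION_COLUMN_PREFIX)]
        records: list[CaseRecord] = []
        for i, row in enumerate(reader, start=2):  # header is row 1
            condition = _parse_enum(
                ConditionCode, row["condition"], row=i, column="condition"
            )
            try:
                age = int(row["age"].strip())
            except ValueError:
                raise LineListError(
                    f"row {i}, column 'age': {row['age']!r} is not an integer"
                ) from None
            criteria = {}
            for col in crit_columns:
                value = tri_from_token(row[col] or "", row=i, column=col)
                if value is not TriValue.UNKNOWN:
                    criteria[col[len(CRITERION_COLUMN_PREFIX) :]] = value
            records.append(
                CaseRecord(
                    case_id=row["case_id"].strip(),
                    condition=condition,
                    age=age,
                    sex=_parse_enum(Sex, row["sex"], row=i, column="sex"),
                    residence=_parse_enum(
                        Residence, row["residence"], row=i, column="residence"
                    ),
                    detection_site=_parse_enum(
                        DetectionSite, row["detection_site"], row=i, column="detection_site"
                    ),
                    criteria=criteria,
                )
            )
    return records


def write_line_list(
    records: Iterable[CaseRecord],
    path: str | Path,
    criterion_ids: Sequence[str] | None = None,
    extra_columns: Mapping[str, Sequence[str]] | None = None,
) -> None:
    """Write case records as a line-list CSV.

    ``criterion_ids`` fixes the criterion column order; by default the sorted
    union of ids appearing in the records is used.  ``extra_columns`` maps
    column name to one value per record (used by the CLI to append
    classification results).
    """
    records = list(records)
    if criterion_ids is None:
        seen: set[str] = set()
        for rec in records:
            seen.update(rec.criteria)
        criterion_ids = sorted(seen)
    extra_columns = dict(extra_columns or {})
    for name, values in extra_columns.items():
        if len(values) != len(records):
            raise ValueError(f"extra column {name!r} has {len(values)} values for {len(records)} records")
    header = (
        list(FIXED_COLUMNS)
        + [CRITERION_COLUMN_PREFIX + cid for cid in criterion_ids]
        + list(extra_columns)
    )
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for idx, rec in enumerate(records):
            row = [
                rec.case_id,
                rec.condition.value,
                str(rec.age),
                rec.sex.value,
                rec.residence.value,
                rec.detection_site.value,
            ]
            row.extend(tri_to_token(rec.criterion(cid)) for cid in criterion_ids)
            row.extend(extra_columns[name][idx] for name in extra_columns)
            writer.writerow(row)
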