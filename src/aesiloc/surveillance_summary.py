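"""Descriptive analysis of classified rosters.

Reproduces the surveillance's reporting surface: the level-of-certainty
distribution per condition and overall, the tabulation of level-4 blocking
reasons, criterion-prevalence tables (n/N over cases with data available),
and a demographics table.

Percent convention throughout: round half up to integer percent; a percent
with zero denominator is undefined and rendered as an em dash, never 0.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .case_model import (
    CaseRecord,
    ConditionCode,
    DetectionSite,
    LOCResult,
    Residence,
    RuleSet,
    Sex,
    TriValue,
)

__all__ = [
    "pct",
    "fmt_pct",
    "LOCBreakdown",
    "LOCDistribution",
    "Level4Reasons",
    "PrevalenceRow",
    "CriterionPrevalenceTable",
    "DemographicsRow",
    "DemographicsTable",
    "summarize_loc",
    "tabulate_level4_reasons",
    "criterion_prevalence",
    "demographics_table",
]

CONFIRMED_LEVELS = (1, 2, 3)
CLASSIFIABLE_LEVELS = (1, 2, 3, 5)

UNDEFINED = "—"  # em dash for 0/0


def pct(n: int, total: int) -> int | None:
    """Integer percent of ``n`` in ``total``, rounded half up; None if total is 0."""
    if total == 0:
        return None
    if not 0 <= n <= total:
        raise ValueError(f"need 0 <= n <= total, got {n}/{total}")
    # floor(100*n/total + 1/2) in exact integer arithmetic
    return (200 * n + total) // (2 * total)


def fmt_pct(value: int | None) -> str:
    return UNDEFINED if value is None else str(value)


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# LOC distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LOCBreakdown:
    """Level counts for one stratum (a condition, or the whole roster)."""

    n_total: int
    counts: Mapping[int, int]  # level -> count, levels 1..5 all present

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("level counts must sum to the stratum total")

    def count(self, *levels: int) -> int:
        return sum(self.counts[lv] for lv in levels)

    def percent(self, *levels: int) -> int | None:
        return pct(self.count(*levels), self.n_total)

    @property
    def confirmed_count(self) -> int:
        return self.count(*CONFIRMED_LEVELS)

    @property
    def confirmed_percent(self) -> int | None:
        return self.percent(*CONFIRMED_LEVELS)

    @property
    def classifiable_count(self) -> int:
        return self.count(*CLASSIFIABLE_LEVELS)

    @property
    def classifiable_percent(self) -> int | None:
        return self.percent(*CLASSIFIABLE_LEVELS)


@dataclass(frozen=True)
class LOCDistribution:
    overall: LOCBreakdown
    per_condition: Mapping[ConditionCode, LOCBreakdown]

    def to_frame(self) -> pd.DataFrame:
        """Counts and percents, one row per condition plus an overall row."""
        rows = []
        items = sorted(self.per_condition.items(), key=lambda kv: kv[0].value)
        for name, bd in [(c.value, bd) for c, bd in items] + [("TOTAL", self.overall)]:
            row: dict[str, object] = {"condition": name, "n": bd.n_total}
            for lv in range(1, 6):
                row[f"level{lv}_n"] = bd.counts[lv]
                row[f"level{lv}_pct"] = fmt_pct(bd.percent(lv))
            row["levels_1_3_n"] = bd.confirmed_count
            row["levels_1_3_pct"] = fmt_pct(bd.confirmed_percent)
            row["classifiable_n"] = bd.classifiable_count
            row["classifiable_pct"] = fmt_pct(bd.classifiable_percent)
            rows.append(row)
        return pd.DataFrame(rows)


def _breakdown(results: Sequence[LOCResult]) -> LOCBreakdown:
    counts = {lv: 0 for lv in range(1, 6)}
    for r in results:
        counts[r.level] += 1
    return LOCBreakdown(n_total=len(results), counts=counts)


def summarize_loc(
    classified: Sequence[tuple[CaseRecord, LOCResult]]
) -> LOCDistribution:
    """Aggregate level counts per condition and overall."""
    if not classified:
        raise ValueError("empty roster")
    by_condition: dict[ConditionCode, list[LOCResult]] = {}
    for case, result in classified:
        by_condition.setdefault(case.condition, []).append(result)
    return LOCDistribution(
        overall=_breakdown([r for _, r in classified]),
        per_condition={c: _breakdown(rs) for c, rs in by_condition.items()},
    )


# ---------------------------------------------------------------------------
# Level-4 reasons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Level4Reasons:
    count: int
    reasons: Counter  # criterion id -> number of level-4 cases it blocks


def tabulate_level4_reasons(
    classified: Sequence[tuple[CaseRecord, LOCResult]]
) -> dict[ConditionCode, Level4Reasons]:
    """Blocking-criterion tallies for the non-classifiable (level 4) cases."""
    counts: dict[ConditionCode, int] = {}
    reasons: dict[ConditionCode, Counter] = {}
    for case, result in classified:
        if result.level != 4:
            continue
        counts[case.condition] = counts.get(case.condition, 0) + 1
        reasons.setdefault(case.condition, Counter()).update(result.blocking_unknowns)
    return {
        c: Level4Reasons(count=counts[c], reasons=reasons[c]) for c in counts
    }


# ---------------------------------------------------------------------------
# Criterion prevalence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrevalenceRow:
    category: str
    label: str
    criterion_id: str
    n: int  # cases with the criterion PRESENT
    n_known: int  # cases with any recorded (non-UNKNOWN) value

    def __post_init__(self) -> None:
        if not 0 <= self.n <= self.n_known:
            raise ValueError("need 0 <= n <= N")

    @property
    def percent(self) -> int | None:
        return pct(self.n, self.n_known)


@dataclass(frozen=True)
class CriterionPrevalenceTable:
    condition: ConditionCode
    n_cases: int
    rows: tuple[PrevalenceRow, ...]

    def row(self, criterion_id: str) -> PrevalenceRow:
        for r in self.rows:
            if r.criterion_id == criterion_id:
                return r
        raise KeyError(criterion_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": r.category,
                    "criterion": r.label,
                    "n": r.n,
                    "N": r.n_known,
                    "percent": fmt_pct(r.percent),
                }
                for r in self.rows
            ]
        )


def criterion_prevalence(
    roster: Sequence[CaseRecord],
    condition: ConditionCode,
    rule_set: RuleSet | None = None,
) -> CriterionPrevalenceTable:
    """Per-criterion n/N among cases of ``condition``.

    ``n`` counts PRESENT values, ``N`` counts cases with any known value;
    criteria never tested in any case show 0/0 (percent undefined).  Rows
    follow the rule set's declared criterion order.
    """
    if rule_set is None:
        from .definitions import builtin_rule_set

        rule_set = builtin_rule_set(condition)
    cases = [c for c in roster if c.condition is condition]
    if not cases:
        raise ValueError(f"no cases of {condition.value} in roster")
    rows = []
    for crit in rule_set.criteria:
        values = [c.criterion(crit.id) for c in cases]
        n_present = sum(v is TriValue.PRESENT for v in values)
        n_known = sum(v is not TriValue.UNKNOWN for v in values)
        rows.append(
            PrevalenceRow(
                category=crit.category.value,
                label=crit.label,
                criterion_id=crit.id,
                n=n_present,
                n_known=n_known,
            )
        )
    return CriterionPrevalenceTable(condition=condition, n_cases=len(cases), rows=tuple(rows))


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicsRow:
    name: str
    n_eopd: int
    n_ipd: int
    age_median: int
    age_min: int
    age_max: int
    n_male: int
    n_addis: int

    @property
    def n_total(self) -> int:
        return self.n_eopd + self.n_ipd


@dataclass(frozen=True)
class DemographicsTable:
    """Per-condition demographics with a total row.

    Condition rows show the detection-site columns as column percents (share
    of all EOPD / all IPD detections); the total row shows them as shares of
    all cases, matching the in-text reporting style.
    """

    rows: tuple[DemographicsRow, ...]
    total: DemographicsRow

    def row(self, condition: ConditionCode) -> DemographicsRow:
        for r in self.rows:
            if r.name == condition.value:
                return r
        raise KeyError(condition)

    def eopd_percent(self, row: DemographicsRow) -> int | None:
        if row is self.total:
            return pct(row.n_eopd, row.n_total)
        return pct(row.n_eopd, self.total.n_eopd)

    def ipd_percent(self, row: DemographicsRow) -> int | None:
        if row is self.total:
            return pct(row.n_ipd, row.n_total)
        return pct(row.n_ipd, self.total.n_ipd)

    def total_percent(self, row: DemographicsRow) -> int | None:
        return pct(row.n_total, self.total.n_total)

    def male_percent(self, row: DemographicsRow) -> int | None:
        return pct(row.n_male, row.n_total)

    def addis_percent(self, row: DemographicsRow) -> int | None:
        return pct(row.n_addis, row.n_total)

    def to_frame(self) -> pd.DataFrame:
        out = []
        for r in (*self.rows, self.total):
            out.append(
                {
                    "condition": r.name,
                    "eopd": f"{r.n_eopd} ({fmt_pct(self.eopd_percent(r))})",
                    "ipd": f"{r.n_ipd} ({fmt_pct(self.ipd_percent(r))})",
                    "total": f"{r.n_total} ({fmt_pct(self.total_percent(r))})",
                    "median_age_range": f"{r.age_median} ({r.age_min}, {r.age_max})",
                    "male": f"{r.n_male} ({fmt_pct(self.male_percent(r))})",
                    "addis_ababa": f"{r.n_addis} ({fmt_pct(self.addis_percent(r))})",
                }
            )
        return pd.DataFrame(out)


def _demographics_row(name: str, cases: Sequence[CaseRecord]) -> DemographicsRow:
    ages = sorted(c.age for c in cases)
    return DemographicsRow(
        name=name,
        n_eopd=sum(c.detection_site is DetectionSite.EOPD for c in cases),
        n_ipd=sum(c.detection_site is DetectionSite.IPD for c in cases),
        age_median=_round_half_up(statistics.median(ages)),
        age_min=ages[0],
        age_max=ages[-1],
        n_male=sum(c.sex is Sex.MALE for c in cases),
        n_addis=sum(c.residence is Residence.ADDIS_ABABA for c in cases),
    )


def demographics_table(roster: Sequence[CaseRecord]) -> DemographicsTable:
    """Detection site, age, sex, and residence summaries per condition.

    Medians of even-sized groups are the mean of the central pair, rounded
    half up to integer years.
    """
    if not roster:
        raise ValueError("empty roster")
    by_condition: dict[ConditionCode, list[CaseRecord]] = {}
    for case in roster:
        by_condition.setdefault(case.condition, []).append(case)
    rows = tuple(
        _demographics_row(c.value, cases)
        for c, cases in sorted(by_condition.items(), key=lambda kv: kv[0].value)
    )
    return DemographicsTable(rows=rows, total=_demographics_row("TOTAL", list(roster)))
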