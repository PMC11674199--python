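"""Synthetic surveillance rosters.

Two sources of cases live here:

* :func:`generate_roster` — a seeded simulator that draws per-criterion
  tri-state values with configurable prevalence and missingness, plus
  demographics, for any mix of conditions.  The study data behind the
  reference tables are not deposited, so simulation is the only way to
  exercise the pipeline at scale.

* :func:`fixture_roster` — a deterministic, hand-authored 203-case roster
  whose per-condition counts, demographics, and criterion patterns encode
  the published aggregate tables of the source surveillance.  Criterion
  patterns are authored minimally: each case carries the smallest set of
  known values consistent with its target level and the published criterion
  marginals; everything untested stays UNKNOWN.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .case_model import (
    CaseRecord,
    ConditionCode,
    DetectionSite,
    Residence,
    Sex,
    TriValue,
)

__all__ = [
    "ConditionSimParams",
    "generate_roster",
    "load_sim_params",
    "fixture_roster",
    "FIXTURE_TOTAL_CASES",
]

FIXTURE_TOTAL_CASES = 203


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class ConditionSimParams:
    """Simulation parameters for one condition's sub-roster."""

    condition: ConditionCode
    n_cases: int
    criterion_prevalence: Mapping[str, float]
    criterion_missingness: Mapping[str, float] = field(default_factory=dict)
    prop_not_a_case: float = 0.0
    exclusion_criterion: str | None = None
    age_median: int = 35
    age_min: int = 0
    age_max: int = 90
    prop_male: float = 0.5
    prop_addis: float = 0.5
    prop_eopd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        for cid, p in self.criterion_prevalence.items():
            _check_prob(f"criterion_prevalence[{cid!r}]", p)
        for cid, p in self.criterion_missingness.items():
            _check_prob(f"criterion_missingness[{cid!r}]", p)
        for name in ("prop_not_a_case", "prop_male", "prop_addis", "prop_eopd"):
            _check_prob(name, getattr(self, name))
        if self.prop_not_a_case > 0 and self.exclusion_criterion is None:
            raise ValueError("exclusion_criterion required when prop_not_a_case > 0")
        if not self.age_min <= self.age_median <= self.age_max:
            raise ValueError("need age_min <= age_median <= age_max")


def _condition_rng(seed: int, condition: ConditionCode) -> np.random.Generator:
    # One stream per condition, derived from (seed, stable hash of the code),
    # so adding or reordering conditions does not perturb the others.
    return np.random.default_rng([seed, zlib.crc32(condition.value.encode())])


def _draw_age(rng: np.random.Generator, lo: int, med: int, hi: int) -> int:
    """Draw an integer age from a balanced two-piece triangular distribution.

    Each half (below / above the median) is picked with probability 1/2 and
    sampled from a triangular density peaked at the median, so the population
    median equals ``med`` exactly while respecting the min/max range.  (A
    single triangular cannot hit arbitrary median/range combinations.)
    """
    if lo == hi:
        return lo
    if rng.random() < 0.5:
        x = float(med) if lo == med else rng.triangular(lo, med, med)
    else:
        x = float(med) if med == hi else rng.triangular(med, med, hi)
    return int(min(max(np.floor(x + 0.5), lo), hi))


def generate_roster(
    params: Sequence[ConditionSimParams], seed: int
) -> list[CaseRecord]:
    """Generate a reproducible synthetic roster.

    Per case, each criterion in ``criterion_prevalence`` is drawn PRESENT
    with its stated prevalence (ABSENT otherwise) and then masked to UNKNOWN
    with its stated missingness.  A ``prop_not_a_case`` fraction of records
    get the exclusion criterion forced to ABSENT (and never masked), making
    them definitively excludable.
    """
    roster: list[CaseRecord] = []
    for p in params:
        rng = _condition_rng(seed, p.condition)
        tag = p.condition.value.lower()
        for i in range(p.n_cases):
            not_a_case = rng.random() < p.prop_not_a_case
            criteria: dict[str, TriValue] = {}
            for cid, prev in p.criterion_prevalence.items():
                value = TriValue.PRESENT if rng.random() < prev else TriValue.ABSENT
                if rng.random() < p.criterion_missingness.get(cid, 0.0):
                    value = TriValue.UNKNOWN
                if value is not TriValue.UNKNOWN:
                    criteria[cid] = value
            if not_a_case:
                criteria[p.exclusion_criterion] = TriValue.ABSENT  # type: ignore[index]
            roster.append(
                CaseRecord(
                    case_id=f"sim-{tag}-{i + 1:05d}",
                    condition=p.condition,
                    age=_draw_age(rng, p.age_min, p.age_median, p.age_max),
                    sex=Sex.MALE if rng.random() < p.prop_male else Sex.FEMALE,
                    residence=(
                        Residence.ADDIS_ABABA
                        if rng.random() < p.prop_addis
                        else Residence.OUTSIDE
                    ),
                    detection_site=(
                        DetectionSite.EOPD
                        if rng.random() < p.prop_eopd
                        else DetectionSite.IPD
                    ),
                    criteria=criteria,
                )
            )
    return roster


def load_sim_params(path: str | Path) -> list[ConditionSimParams]:
    """Read a JSON array of simulation parameter objects."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, list):
        raise ValueError("simulation parameter file must contain a JSON array")
    out = []
    for i, item in enumerate(doc):
        if not isinstance(item, dict) or "condition" not in item or "n_cases" not in item:
            raise ValueError(f"params[{i}]: expected an object with condition and n_cases")
        try:
            condition = ConditionCode(item["condition"])
        except ValueError:
            raise ValueError(f"params[{i}]: unknown condition {item['condition']!r}") from None
        kwargs = {k: v for k, v in item.items() if k != "condition"}
        kwargs.setdefault("criterion_prevalence", {})
        out.append(ConditionSimParams(condition=condition, **kwargs))
    return out


# ---------------------------------------------------------------------------
# Hand-authored fixture roster
# ---------------------------------------------------------------------------

P = TriValue.PRESENT
A = TriValue.ABSENT

_GBS_BASE = {
    "bilateral_weakness": P,
    "flaccid_weakness": P,
    "dtr_decreased_in_weak_limbs": P,
    "onset_nadir_12h_28d": P,
    "alt_dx_absent": P,
}

_CNS_LEVEL4 = {"focal_cns_sign": P}  # all four inflammation indicators UNKNOWN


def _gbs_patterns() -> list[dict[str, TriValue]]:
    # Authored to the published criterion marginals: 11/11 bilateral weakness
    # and nadir window, 10/11 reflex loss and no-alternative-diagnosis, 7/8
    # consistent electrophysiology (3 untested), CSF examined in one case
    # only (with cytoalbuminologic dissociation, electrophysiology untested).
    pats: list[dict[str, TriValue]] = []
    pats.append({**_GBS_BASE, "csf_wbc_lt50": P, "csf_protein_elevated": P})  # level 2
    for _ in range(7):  # level 2 via electrophysiology
        pats.append({**_GBS_BASE, "electrophys_consistent": P})
    pats.append({**_GBS_BASE, "electrophys_consistent": A})  # level 3
    pats.append(dict(_GBS_BASE))  # level 3, nothing tested
    pats.append(  # level 5: alternative diagnosis found, reflexes preserved
        {**_GBS_BASE, "dtr_decreased_in_weak_limbs": A, "alt_dx_absent": A}
    )
    return pats


def _convulsion_patterns() -> list[dict[str, TriValue]]:
    base = {"generalized_motor_seizure": P, "bilateral_motor": P, "loss_of_consciousness": P}
    pats = [{**base, "witnessed_by_clinician": P, "eeg_epileptiform": P} for _ in range(3)]
    pats += [{**base, "witnessed_by_clinician": P} for _ in range(27)]
    pats += [{**base, "witnessed_by_clinician": A} for _ in range(7)]
    # the one non-classifiable seizure: laterality of movements undocumented
    pats.append(
        {
            "generalized_motor_seizure": P,
            "loss_of_consciousness": P,
            "witnessed_by_clinician": A,
            "eeg_epileptiform": A,
        }
    )
    return pats


def _myocarditis_patterns() -> list[dict[str, TriValue]]:
    pats = [
        {"compatible_symptoms": P, "biomarker_elevated": P, "echo_abnormal": P, "ecg_abnormal": P}
        for _ in range(2)  # level 1
    ]
    pats += [
        {"compatible_symptoms": P, "biomarker_elevated": P, "ecg_abnormal": P}
        for _ in range(6)  # level 2
    ]
    pats += [
        {"compatible_symptoms": P, "biomarker_elevated": A, "ecg_abnormal": P}
        for _ in range(2)  # level 3
    ]
    pats += [
        {"compatible_symptoms": A, "biomarker_elevated": A, "ecg_abnormal": A}
        for _ in range(2)  # level 5
    ]
    return pats


def _pericarditis_patterns() -> list[dict[str, TriValue]]:
    pats = [
        {"typical_chest_pain": P, "pericardial_rub": A, "ecg_typical": P, "effusion_imaging": P}
        for _ in range(2)  # level 1
    ]
    pats += [
        {"typical_chest_pain": P, "pericardial_rub": A, "ecg_typical": P}
        for _ in range(5)  # level 2
    ]
    pats += [
        {
            "typical_chest_pain": P,
            "pericardial_rub": A,
            "ecg_typical": A,
            "effusion_imaging": A,
            "chest_radiograph_suggestive": P,
        }
        for _ in range(2)  # level 3
    ]
    # two level-4 cases: ECG, chest radiograph and effusion imaging unknown
    pats += [{"typical_chest_pain": P, "pericardial_rub": A} for _ in range(2)]
    pats.append({"typical_chest_pain": A, "pericardial_rub": A})  # level 5
    return pats


def _thrombocytopenia_patterns() -> list[dict[str, TriValue]]:
    pats = [{"platelet_lt150": P, "platelet_lt150_repeat": P} for _ in range(10)]
    pats += [{"platelet_lt150": P, "bleeding_symptoms": P} for _ in range(8)]
    pats += [{"platelet_lt150": P} for _ in range(5)]
    return pats


def _thrombosis_patterns() -> list[dict[str, TriValue]]:
    base = {"clinical_diagnosis_documented": P}
    pats = [{**base, "imaging_confirmed": P, "symptoms_at_site": P} for _ in range(60)]
    pats += [{**base, "imaging_confirmed": P} for _ in range(25)]
    pats += [dict(base) for _ in range(13)]
    pats += [{"clinical_diagnosis_documented": A} for _ in range(2)]  # level 5
    return pats


@dataclass(frozen=True)
class _FixtureBlock:
    condition: ConditionCode
    prefix: str
    patterns: tuple[dict[str, TriValue], ...]
    ages: tuple[int, ...]
    n_eopd: int
    n_male: int
    n_addis: int

    def __post_init__(self) -> None:
        n = len(self.patterns)
        assert len(self.ages) == n and max(self.n_eopd, self.n_male, self.n_addis) <= n


def _filler_ages(lo: int, med: int, hi: int, n: int) -> tuple[int, ...]:
    if n == 1:
        return (med,)
    return (lo,) + (med,) * (n - 2) + (hi,)


def _fixture_blocks() -> list[_FixtureBlock]:
    # Thrombosis ages are spread so that the whole-roster median lands on the
    # published overall median (38) while keeping the condition median at 49.
    thrombosis_ages = (16,) + (38,) * 4 + (49,) * 46 + (50,) * 48 + (88,)
    return [
        _FixtureBlock(
            ConditionCode.ADEM, "adem",
            tuple({"multifocal_cns_deficits": P, "alt_dx_absent": A} for _ in range(2)),
            (21, 26), n_eopd=1, n_male=0, n_addis=2,
        ),
        _FixtureBlock(
            ConditionCode.BELLS_PALSY, "bp",
            ({"unilateral_facial_weakness": P, "alt_dx_absent": A},),
            (52,), n_eopd=1, n_male=1, n_addis=0,
        ),
        _FixtureBlock(
            ConditionCode.ENCEPHALITIS, "enc",
            tuple(dict(_CNS_LEVEL4) for _ in range(2)),
            (21, 26), n_eopd=1, n_male=0, n_addis=2,
        ),
        _FixtureBlock(
            ConditionCode.GBS_FISHER, "gbs",
            tuple(_gbs_patterns()),
            _filler_ages(15, 26, 58, 11), n_eopd=7, n_male=4, n_addis=6,
        ),
        _FixtureBlock(
            ConditionCode.GENERALIZED_CONVULSION, "gc",
            tuple(_convulsion_patterns()),
            _filler_ages(14, 31, 82, 38), n_eopd=35, n_male=22, n_addis=34,
        ),
        _FixtureBlock(
            ConditionCode.MYELITIS, "mye",
            tuple(dict(_CNS_LEVEL4) for _ in range(2)),
            (21, 26), n_eopd=1, n_male=0, n_addis=2,
        ),
        _FixtureBlock(
            ConditionCode.MYOCARDITIS, "myo",
            tuple(_myocarditis_patterns()),
            _filler_ages(17, 29, 83, 12), n_eopd=1, n_male=8, n_addis=6,
        ),
        _FixtureBlock(
            ConditionCode.PERICARDITIS, "per",
            tuple(_pericarditis_patterns()),
            _filler_ages(17, 29, 83, 12), n_eopd=1, n_male=8, n_addis=6,
        ),
        _FixtureBlock(
            ConditionCode.THROMBOCYTOPENIA, "tcp",
            tuple(_thrombocytopenia_patterns()),
            _filler_ages(13, 35, 62, 23), n_eopd=21, n_male=9, n_addis=13,
        ),
        _FixtureBlock(
            ConditionCode.THROMBOSIS_THROMBOEMBOLISM, "tte",
            tuple(_thrombosis_patterns()),
            thrombosis_ages, n_eopd=93, n_male=32, n_addis=46,
        ),
    ]


def fixture_roster() -> list[CaseRecord]:
    """The deterministic 203-case reference roster.

    Per-condition counts, detection-site split, sex, residence, and age
    medians/ranges reproduce the published demographics table; criterion
    patterns are authored so the shipped rule sets derive the published
    level-of-certainty distribution (187 at levels 1-3, 7 at level 4, 9 at
    level 5).
    """
    roster: list[CaseRecord] = []
    for block in _fixture_blocks():
        for i, (pattern, age) in enumerate(zip(block.patterns, block.ages)):
            roster.append(
                CaseRecord(
                    case_id=f"{block.prefix}-{i + 1:03d}",
                    condition=block.condition,
                    age=age,
                    sex=Sex.MALE if i < block.n_male else Sex.FEMALE,
                    residence=(
                        Residence.ADDIS_ABABA if i < block.n_addis else Residence.OUTSIDE
                    ),
                    detection_site=(
                        DetectionSite.EOPD if i < block.n_eopd else DetectionSite.IPD
                    ),
                    criteria=pattern,
                )
            )
    assert len(roster) == FIXTURE_TOTAL_CASES
    return roster
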