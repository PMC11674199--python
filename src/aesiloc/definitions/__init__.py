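"""Shipped declarative rule sets and rule-set file handling.

One JSON document per condition, named ``<condition_code_lowercase>.json``.
Schema::

    {
      "condition": "<ConditionCode>",
      "version": "<free text>",
      "criteria": [{"id": ..., "label": ..., "category": ...}, ...],
      "levels": {
        "1": <expr>, "2": <expr>, "3": <expr>
      }
    }

where ``<expr>`` is either a bare criterion id (atom) or a nested array:
``["ALL", ...]``, ``["ANY", ...]``, ``["AT_LEAST", k, ...]``, ``["NOT", x]``.

Only the Guillain-Barré set is transcribed from published level logic; the
other sets are simplified stand-ins that are internally nested and tri-state
aware (see the criteria labels for intent).  Replacing one is a data change:
drop a new JSON file into the rules directory.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from ..case_model import (
    AllOf,
    AnyOf,
    AtLeast,
    Atom,
    ConditionCode,
    CriterionCategory,
    CriterionDef,
    Not,
    RuleExpr,
    RuleSet,
    TriValue,
    expr_atoms,
)
from ..logic_engine import TriBool, eval_expr

__all__ = [
    "RuleSetSchemaError",
    "ValidationReport",
    "parse_rule_expr",
    "rule_set_from_dict",
    "load_rule_set",
    "load_rule_set_dir",
    "validate_rule_set",
    "builtin_rules_dir",
    "builtin_rule_set",
    "builtin_rule_sets",
    "gbs_rule_set",
    "MAX_VALIDATION_ATOMS",
]

MAX_VALIDATION_ATOMS = 20


class RuleSetSchemaError(ValueError):
    """Schema violation in a rule-set document, with a JSON-pointer path."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


def parse_rule_expr(node: object, pointer: str = "") -> RuleExpr:
    """Parse the nested-array expression serialization."""
    if isinstance(node, str):
        return Atom(node)
    if not isinstance(node, list) or not node:
        raise RuleSetSchemaError(pointer or "/", "expected criterion id or non-empty array")
    op = node[0]
    if op == "NOT":
        if len(node) != 2:
            raise RuleSetSchemaError(pointer, "NOT takes exactly one operand")
        return Not(parse_rule_expr(node[1], f"{pointer}/1"))
    if op in ("ALL", "ANY"):
        if len(node) < 2:
            raise RuleSetSchemaError(pointer, f"{op} requires at least one operand")
        children = tuple(
            parse_rule_expr(child, f"{pointer}/{i}") for i, child in enumerate(node[1:], 1)
        )
        return AllOf(children) if op == "ALL" else AnyOf(children)
    if op == "AT_LEAST":
        if len(node) < 3 or not isinstance(node[1], int):
            raise RuleSetSchemaError(pointer, "AT_LEAST requires an integer k and operands")
        children = tuple(
            parse_rule_expr(child, f"{pointer}/{i}") for i, child in enumerate(node[2:], 2)
        )
        try:
            return AtLeast(node[1], children)
        except ValueError as exc:
            raise RuleSetSchemaError(pointer, str(exc)) from None
    raise RuleSetSchemaError(pointer, f"unknown operator {op!r}")


def rule_set_from_dict(doc: object) -> RuleSet:
    """Build a validated :class:`RuleSet` from a parsed JSON document."""
    if not isinstance(doc, dict):
        raise RuleSetSchemaError("/", "document must be a JSON object")
    for key in ("condition", "criteria", "levels"):
        if key not in doc:
            raise RuleSetSchemaError(f"/{key}", "missing required key")
    try:
        condition = ConditionCode(doc["condition"])
    except ValueError:
        raise RuleSetSchemaError("/condition", f"unknown condition code {doc['condition']!r}") from None
    if not isinstance(doc["criteria"], list) or not doc["criteria"]:
        raise RuleSetSchemaError("/criteria", "must be a non-empty array")
    criteria = []
    for i, item in enumerate(doc["criteria"]):
        ptr = f"/criteria/{i}"
        if not isinstance(item, dict):
            raise RuleSetSchemaError(ptr, "criterion must be an object")
        for key in ("id", "label", "category"):
            if key not in item:
                raise RuleSetSchemaError(f"{ptr}/{key}", "missing required key")
        try:
            category = CriterionCategory(item["category"])
        except ValueError:
            raise RuleSetSchemaError(
                f"{ptr}/category", f"unknown category {item['category']!r}"
            ) from None
        criteria.append(CriterionDef(id=item["id"], label=item["label"], category=category))
    levels = doc["levels"]
    if not isinstance(levels, dict) or set(levels) != {"1", "2", "3"}:
        raise RuleSetSchemaError("/levels", 'must be an object with keys "1", "2", "3"')
    exprs = {k: parse_rule_expr(levels[k], f"/levels/{k}") for k in ("1", "2", "3")}
    try:
        return RuleSet(
            condition=condition,
            criteria=tuple(criteria),
            level1=exprs["1"],
            level2=exprs["2"],
            level3=exprs["3"],
            version=str(doc.get("version", "")),
        )
    except ValueError as exc:  # duplicate ids / dangling atoms
        raise RuleSetSchemaError("/", str(exc)) from None


def load_rule_set(path: str | Path) -> RuleSet:
    """Load and validate one rule-set JSON file."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise RuleSetSchemaError("/", f"{path}: invalid JSON ({exc})") from None
    return rule_set_from_dict(doc)


def load_rule_set_dir(directory: str | Path) -> dict[ConditionCode, RuleSet]:
    """Load every ``*.json`` rule set in a directory, keyed by condition."""
    out: dict[ConditionCode, RuleSet] = {}
    for path in sorted(Path(directory).glob("*.json")):
        rules = load_rule_set(path)
        if rules.condition in out:
            raise RuleSetSchemaError("/condition", f"duplicate rule set for {rules.condition.value}")
        out[rules.condition] = rules
    return out


# ---------------------------------------------------------------------------
# Nesting validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    """Result of exhaustive specificity-nesting validation."""

    condition: ConditionCode
    n_atoms: int
    n_assignments: int
    counterexamples: tuple[dict[str, TriValue], ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.counterexamples


def _known_assignments(atoms: tuple[str, ...]) -> Iterator[dict[str, TriValue]]:
    for values in itertools.product((TriValue.PRESENT, TriValue.ABSENT), repeat=len(atoms)):
        yield dict(zip(atoms, values))


def validate_rule_set(rules: RuleSet, max_counterexamples: int = 5) -> ValidationReport:
    """Check level1 ⇒ level2 ⇒ level3 over every fully-known assignment.

    Enumerates all 2^n assignments over the atoms used by the three level
    predicates; refuses rule sets with more than ``MAX_VALIDATION_ATOMS``
    atoms (combinatorial guard).
    """
    atoms = tuple(
        sorted(expr_atoms(rules.level1) | expr_atoms(rules.level2) | expr_atoms(rules.level3))
    )
    if len(atoms) > MAX_VALIDATION_ATOMS:
        raise ValueError(
            f"rule set for {rules.condition.value} has {len(atoms)} atoms; "
            f"exhaustive validation is limited to {MAX_VALIDATION_ATOMS}"
        )
    counterexamples: list[dict[str, TriValue]] = []
    n = 0
    for assignment in _known_assignments(atoms):
        n += 1
        truths = [eval_expr(rules.level(k), assignment) is TriBool.TRUE for k in (1, 2, 3)]
        if (truths[0] and not truths[1]) or (truths[1] and not truths[2]):
            if len(counterexamples) < max_counterexamples:
                counterexamples.append(assignment)
    return ValidationReport(
        condition=rules.condition,
        n_atoms=len(atoms),
        n_assignments=n,
        counterexamples=tuple(counterexamples),
    )


# ---------------------------------------------------------------------------
# Shipped rule sets
# ---------------------------------------------------------------------------


def builtin_rules_dir() -> Path:
    """Directory holding the shipped rule-set JSON files."""
    return Path(resources.files(__package__))  # type: ignore[arg-type]


def builtin_rule_set(condition: ConditionCode) -> RuleSet:
    return load_rule_set(builtin_rules_dir() / f"{condition.value.lower()}.json")


def builtin_rule_sets() -> dict[ConditionCode, RuleSet]:
    return load_rule_set_dir(builtin_rules_dir())


def gbs_rule_set() -> RuleSet:
    """The Guillain-Barré / Fisher rule set (the only fully transcribed one)."""
    return builtin_rule_set(ConditionCode.GBS_FISHER)
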