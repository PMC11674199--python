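"""Three-valued rule evaluation and level-of-certainty assignment.

Rule expressions are evaluated under strong Kleene semantics: a connective
returns TRUE or FALSE only when every completion of the UNKNOWN inputs would
agree.  Classification tries the level predicates from most specific (1) to
most sensitive (3); the first TRUE wins.  If none is TRUE the case is either
definitively excluded (level 5, when the level-3 predicate is FALSE) or
non-classifiable for lack of information (level 4).
"""

from __future__ import annotations

import enum
from typing import Mapping

from .case_model import (
    AllOf,
    AnyOf,
    AtLeast,
    Atom,
    CaseRecord,
    LOCResult,
    Not,
    RuleExpr,
    RuleSet,
    TriValue,
    expr_atoms,
)

__all__ = ["TriBool", "ContractError", "eval_expr", "classify_case", "explain_level4"]


class ContractError(ValueError):
    """A precondition of the classification API was violated by the caller."""


class TriBool(enum.Enum):
    """Kleene truth value of a rule expression."""

    FALSE = 0
    UNKNOWN = 1
    TRUE = 2

    def __invert__(self) -> "TriBool":
        return TriBool(2 - self.value)

    def __and__(self, other: "TriBool") -> "TriBool":
        return TriBool(min(self.value, other.value))

    def __or__(self, other: "TriBool") -> "TriBool":
        return TriBool(max(self.value, other.value))

    @classmethod
    def from_trivalue(cls, value: TriValue) -> "TriBool":
        return {
            TriValue.PRESENT: cls.TRUE,
            TriValue.ABSENT: cls.FALSE,
            TriValue.UNKNOWN: cls.UNKNOWN,
        }[value]


def eval_expr(expr: RuleExpr, assignment: Mapping[str, TriValue]) -> TriBool:
    """Evaluate ``expr`` under strong Kleene semantics.

    Criterion ids missing from ``assignment`` read as UNKNOWN, so this is a
    total function over valid expressions.
    """
    if isinstance(expr, Atom):
        return TriBool.from_trivalue(assignment.get(expr.criterion, TriValue.UNKNOWN))
    if isinstance(expr, Not):
        return ~eval_expr(expr.child, assignment)
    if isinstance(expr, AllOf):
        out = TriBool.TRUE
        for child in expr.children:
            out &= eval_expr(child, assignment)
        return out
    if isinstance(expr, AnyOf):
        out = TriBool.FALSE
        for child in expr.children:
            out |= eval_expr(child, assignment)
        return out
    if isinstance(expr, AtLeast):
        results = [eval_expr(child, assignment) for child in expr.children]
        n_true = sum(r is TriBool.TRUE for r in results)
        n_unknown = sum(r is TriBool.UNKNOWN for r in results)
        if n_true >= expr.k:
            return TriBool.TRUE
        if n_true + n_unknown < expr.k:
            return TriBool.FALSE
        return TriBool.UNKNOWN
    raise TypeError(f"not a rule expression: {expr!r}")


def _unknown_atoms(expr: RuleExpr, assignment: Mapping[str, TriValue]) -> frozenset[str]:
    return frozenset(
        a for a in expr_atoms(expr) if assignment.get(a, TriValue.UNKNOWN) is TriValue.UNKNOWN
    )


def _false_literals(
    expr: RuleExpr, assignment: Mapping[str, TriValue], positive: bool = True
) -> frozenset[str]:
    """Atoms whose known value contradicts their (polarity-adjusted) occurrence."""
    if isinstance(expr, Atom):
        value = assignment.get(expr.criterion, TriValue.UNKNOWN)
        failing = TriValue.ABSENT if positive else TriValue.PRESENT
        return frozenset((expr.criterion,)) if value is failing else frozenset()
    if isinstance(expr, Not):
        return _false_literals(expr.child, assignment, not positive)
    out: set[str] = set()
    for child in expr.children:
        out |= _false_literals(child, assignment, positive)
    return frozenset(out)


def classify_case(case: CaseRecord, rules: RuleSet) -> LOCResult:
    """Assign the level of certainty for one case.

    Levels 1-3 are tried in order and the first predicate that is TRUE wins.
    Otherwise the case is level 5 when the level-3 (most sensitive) predicate
    is definitively FALSE, and level 4 when it is UNKNOWN.  For level 4 the
    blocking unknowns are the UNKNOWN-valued atoms of the level-3 predicate —
    the one whose confirmation the missing data blocks (levels 1 and 2 cannot
    hold either, by nesting).  For level 5 the failed criteria are the
    level-3 atoms whose recorded values definitively fail.
    """
    if case.condition is not rules.condition:
        raise ContractError(
            f"case {case.case_id!r} has condition {case.condition.value}, "
            f"rule set is for {rules.condition.value}"
        )
    assignment = case.criteria
    for k in (1, 2, 3):
        if eval_expr(rules.level(k), assignment) is TriBool.TRUE:
            return LOCResult(level=k, satisfied_level=k)
    level3 = eval_expr(rules.level3, assignment)
    if level3 is TriBool.FALSE:
        return LOCResult(level=5, failed_criteria=_false_literals(rules.level3, assignment))
    # level3 is UNKNOWN: resolving its unknown atoms forces a definite level.
    return LOCResult(level=4, blocking_unknowns=_unknown_atoms(rules.level3, assignment))


def explain_level4(case: CaseRecord, rules: RuleSet) -> frozenset[str]:
    """Criterion ids whose UNKNOWN values keep ``case`` at level 4.

    Resolving every returned criterion to a known value forces a level in
    {1, 2, 3, 5}.  Calling this on a case that is not level 4 is a
    :class:`ContractError`.
    """
    result = classify_case(case, rules)
    if result.level != 4:
        raise ContractError(
            f"case {case.case_id!r} classified at level {result.level}, not level 4"
        )
    return result.blocking_unknowns
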