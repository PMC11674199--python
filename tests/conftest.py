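import pytest

from aesiloc.case_model import ConditionCode
from aesiloc.definitions import builtin_rule_sets
from aesiloc.logic_engine import classify_case
from aesiloc.synthetic_cases import fixture_roster


@pytest.fixture(scope="session")
def rule_sets():
    return builtin_rule_sets()


@pytest.fixture(scope="session")
def gbs_rules(rule_sets):
    return rule_sets[ConditionCode.GBS_FISHER]


@pytest.fixture(scope="session")
def roster():
    return fixture_roster()


@pytest.fixture(scope="session")
def classified(roster, rule_sets):
    return [(case, classify_case(case, rule_sets[case.condition])) for case in roster]
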