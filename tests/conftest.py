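import pytest

from vancalc import (
    builtin_adult_table,
    builtin_pediatric_table,
    standard_infusion_rule,
)


@pytest.fixture(scope="session")
def adult_table():
    return builtin_adult_table()


@pytest.fixture(scope="session")
def pediatric_table():
    return builtin_pediatric_table()


@pytest.fixture(scope="session")
def rule():
    return standard_infusion_rule()


@pytest.fixture(scope="session", params=["adult", "pediatric"])
def any_table(request, adult_table, pediatric_table):
    return adult_table if request.param == "adult" else pediatric_table
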