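import pytest
from hypothesis import settings as hyp_settings

from wcdcma import LifeTable, load_parameters, synthetic_life_table

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


def flat_life_table(q: float = 0.01, min_age: int = 60, max_age: int = 110) -> LifeTable:
    """Constant-mortality table (terminal age absorbing), handy for hand oracles."""
    ages = tuple(range(min_age, max_age + 1))
    qs = tuple(q for _ in ages[:-1]) + (1.0,)
    return LifeTable(ages=ages, q_annual=qs)


def immortal_life_table(min_age: int = 60, max_age: int = 110) -> LifeTable:
    ages = tuple(range(min_age, max_age + 1))
    return LifeTable(ages=ages, q_annual=tuple(0.0 for _ in ages[:-1]) + (1.0,))


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return synthetic_life_table()


@pytest.fixture(scope="session")
def base_params(life_table):
    """All-defaults parameter bundle on the default synthetic life table."""
    return load_parameters(None, life_table)
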