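import importlib.resources

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mortrend.icd import GCMap
from mortrend.redistribution import load_weight_table

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gc_map() -> GCMap:
    ref = importlib.resources.files("mortrend.data") / "gc_map_default_synthetic.yaml"
    with importlib.resources.as_file(ref) as p:
        return GCMap.from_yaml(p)


@pytest.fixture(scope="session")
def weight_table() -> pd.DataFrame:
    ref = importlib.resources.files("mortrend.data") / "weights_default_synthetic.csv"
    with importlib.resources.as_file(ref) as p:
        return load_weight_table(p)


@pytest.fixture(scope="session")
def rate_fixture():
    from mortrend.io import brazil_adolescent_rates
    return brazil_adolescent_rates()


def make_records(year=2015, sexes=("male",), ages=(16,), causes=("X70",),
                 weights=None) -> pd.DataFrame:
    """Small canonical record frame for hand-built scenarios."""
    from mortrend.io import age_group_of
    n = max(len(sexes), len(ages), len(causes))
    sexes = list(sexes) * (n // len(sexes) or 1)
    ages = list(ages) * (n // len(ages) or 1)
    causes = list(causes) * (n // len(causes) or 1)
    ag = [age_group_of(a) for a in ages]
    return pd.DataFrame({
        "year": year, "sex": sexes[:n],
        "age_years": [np.nan if a is None else float(a) for a in ages[:n]],
        "age_group": ag[:n], "cause": causes[:n],
        "weight": 1.0 if weights is None else weights,
    })


def random_records(rng: np.random.Generator, n: int = 300) -> pd.DataFrame:
    """Random record frame exercising suicides, garbage codes, other causes
    and missing demographics."""
    from mortrend.io import age_group_of
    causes = rng.choice(
        ["X70", "X72", "X64", "X80", "Y20", "Y30", "R99", "X59",
         "X95", "V43", "W74", "I21"], size=n)
    sexes = rng.choice(["male", "female", "unknown"], p=[0.55, 0.40, 0.05], size=n)
    ages = rng.integers(10, 20, size=n).astype(float)
    ages[rng.random(n) < 0.05] = np.nan
    years = rng.choice([2010, 2011, 2012], size=n)
    return pd.DataFrame({
        "year": years, "sex": sexes, "age_years": ages,
        "age_group": [age_group_of(a) for a in ages],
        "cause": causes, "weight": 1.0,
    })
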