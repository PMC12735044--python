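import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from labscreen.datasets import table1_fixture, table2_fixture, table3_fixture
from labscreen.matrix import IndicatorMatrix, IndicatorSpec

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture(scope="session")
def table3():
    return table3_fixture()


@pytest.fixture
def small_matrix():
    """3 strains x 3 positive indicators, fixed values."""
    values = pd.DataFrame(
        [[2.0, 30.0, 400.0], [5.0, 10.0, 900.0], [3.0, 20.0, 650.0]],
        index=["A", "B", "C"],
        columns=["x", "y", "z"],
    )
    return IndicatorMatrix(values)


def random_positive_matrix(rng, n_strains=None, n_indicators=None):
    """Random strictly positive matrix on mixed scales."""
    n = n_strains or rng.integers(3, 7)
    p = n_indicators or rng.integers(2, 6)
    scales = rng.uniform(1.0, 1000.0, size=p)
    values = rng.uniform(0.1, 1.0, size=(n, p)) * scales
    df = pd.DataFrame(
        values,
        index=[f"S{i}" for i in range(n)],
        columns=[f"I{j}" for j in range(p)],
    )
    return IndicatorMatrix(df)


def matrix_with_orientation(m, orientations):
    specs = [IndicatorSpec(s.name, o, s.unit) for s, o in zip(m.specs, orientations)]
    return IndicatorMatrix(m.values, specs, m.sds)
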