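import numpy as np
import pandas as pd
import pytest

from raincloudpy import SimSpec, simulate_repeated_measures, simulate_two_groups


@pytest.fixture(scope="session")
def two_group_table() -> pd.DataFrame:
    """250 observations per group, skewed vs normal, with the second factor."""
    return simulate_two_groups(SimSpec(250, 50.0, 25.0, seed=20, second_factor=True))


@pytest.fixture(scope="session")
def factorial_table() -> pd.DataFrame:
    """2 groups (n=18/11) x 3 timepoints."""
    return simulate_repeated_measures(seed=20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def scale_to_sd(values, target_sd: float, target_mean: float = 0.0) -> np.ndarray:
    """Affinely rescale a sample so its (ddof=1) sd and mean are exact."""
    v = np.asarray(values, float)
    s = v.std(ddof=1)
    return target_mean + (v - v.mean()) * (target_sd / s)
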