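import numpy as np
import pytest

from gadnn import SimConfig, dataset_from_arrays, generate
from gadnn.data import FEATURES


@pytest.fixture(scope="session")
def small_cohort():
    """120-subject cohort with default dimorphism/age trends."""
    return generate(SimConfig(n=120, seed=42))


@pytest.fixture(scope="session")
def table2_cohort():
    """Cohort whose age-group sizes match the 39/70/90/40 distribution."""
    sizes = {"A": 39, "B": 70, "C": 90, "D": 40}
    mids = {"A": 21, "B": 30, "C": 38, "D": 46}
    ages = np.concatenate([np.full(n, mids[g]) for g, n in sizes.items()])
    ages = ages + np.linspace(-2, 2, len(ages))  # spread inside each bin
    rng = np.random.default_rng(0)
    X = rng.lognormal(mean=3.0, sigma=0.2, size=(len(ages), len(FEATURES)))
    sex = rng.choice(["F", "M"], size=len(ages))
    return dataset_from_arrays(X, sex, ages)
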