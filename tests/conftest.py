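import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from orthomibg.simulate import SimulationParams, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient synthetic cohort with tilt series, fixed seed."""
    params = SimulationParams(n_patients=300)
    cohort, tilt = generate_cohort(params, seed=11)
    return cohort, tilt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def mediation_frame(rng):
    """Random continuous data with a known linear mediation structure."""
    n = 400
    age = rng.normal(70, 9, n)
    dur = rng.normal(1.1, 1.0, n)
    a = rng.normal(1.55, 0.37, n)
    b = 10 - 8.0 * a + 0.1 * age + rng.normal(0, 10, n)
    c = 0.5 - 0.4 * a + 0.01 * b + 0.005 * age + 0.05 * dur + rng.normal(0, 0.6, n)
    return pd.DataFrame({"a": a, "b": b, "c": c, "age": age, "duration": dur})
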