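import numpy as np
import pytest

from adcresponse import DoseSchedule, ModelParams, weekly_schedule


@pytest.fixture
def schedule() -> DoseSchedule:
    """Weekly 0.1 mg dosing from day 7 through day 84."""
    return weekly_schedule(n_doses=12)


@pytest.fixture
def no_dose() -> DoseSchedule:
    return DoseSchedule(n_doses=0)


@pytest.fixture
def params() -> ModelParams:
    return ModelParams(rho=0.3, mu_H=5.0, z=0.3, q=1e-3, gamma=1.0, C0=1e4)


@pytest.fixture
def day_grid() -> np.ndarray:
    return np.arange(0.0, 151.0)


def random_params(rng: np.random.Generator) -> ModelParams:
    """Valid parameter set drawn from the tabulated biological ranges."""
    return ModelParams(
        rho=rng.uniform(0.2, 0.5),
        mu_H=rng.uniform(1.0, 10.0),
        z=rng.uniform(0.0, 1.0),
        q=rng.uniform(0.0, 1.0),
        gamma=rng.uniform(0.0, 1.0),
        C0=10.0 ** rng.uniform(2.0, 6.0),
    )
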