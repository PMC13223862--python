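import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tsacea

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published_inputs():
    """Packaged published parameter set: (arms, utilities, run config)."""
    return tsacea.load_published_parameters()


@pytest.fixture(scope="session")
def us_lt():
    return tsacea.us2021_synthetic()


@pytest.fixture(scope="session")
def immortal_lt():
    """qx = 0 over a wide span (terminal closure far beyond any horizon)."""
    law = tsacea.SyntheticMortalityLaw(
        law="constant_hazard", qx=0.0, age_min=40, age_max=130
    )
    return tsacea.make_life_table(law)


@pytest.fixture(scope="session")
def flat_lt():
    """Constant annual death probability 0.02 (geometric-series oracle)."""
    law = tsacea.SyntheticMortalityLaw(
        law="constant_hazard", qx=0.02, age_min=40, age_max=130
    )
    return tsacea.make_life_table(law)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
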