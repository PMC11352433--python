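import numpy as np
import pytest

from dcsflow import (
    CorrelatorConfig,
    OpticalConfig,
    delay_schedule,
    derive_constants,
)


@pytest.fixture(scope="session")
def tissue_optics():
    """Generic forearm-tissue optics at 785 nm, 1 cm separation."""
    return OpticalConfig.from_nm(mu_a=0.1, mu_s_prime=10.0, rho=1.0)


@pytest.fixture(scope="session")
def tissue_constants(tissue_optics):
    return derive_constants(tissue_optics)


@pytest.fixture(scope="session")
def preset80():
    return CorrelatorConfig.preset_80()


@pytest.fixture(scope="session")
def schedule80(preset80):
    return delay_schedule(preset80)
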