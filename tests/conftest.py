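import numpy as np
import pytest

from uccea import CHECKMATE_901, calibrate_family
from uccea.pipeline import RunConfig, build_base_case


@pytest.fixture(scope="session")
def base_config():
    return RunConfig(seed=1, run_psa=False, run_owsa=False, run_threshold=False)


@pytest.fixture(scope="session")
def base_model(base_config):
    """Base-case model with calibrated survival evidence (shared, read-only)."""
    return build_base_case(base_config)


@pytest.fixture(scope="session")
def calibrated_params():
    """Calibrated family parameters for all four arm/endpoint curves."""
    return {key: calibrate_family(cal) for key, cal in CHECKMATE_901.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20261)
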