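import warnings

import pytest

from pulsedrug.model_core import AlternationSchedule, ModelParameters


@pytest.fixture
def default_params() -> ModelParameters:
    """Perfect biostatic drug with the default rates, K=1000."""
    return ModelParameters.create(fS_drug=0.0, K=1000)


@pytest.fixture
def biocidal_params() -> ModelParameters:
    """Biocidal drug just above the MIC (g'_S = 1.1), K=1000."""
    return ModelParameters.create(fS_drug=1.0, gS_drug=1.1, K=1000)


@pytest.fixture
def small_K_params() -> ModelParameters:
    return ModelParameters.create(fS_drug=0.0, K=100)


@pytest.fixture
def schedule_T1000() -> AlternationSchedule:
    return AlternationSchedule(period=1000.0)


@pytest.fixture(autouse=True)
def _no_unraisable_warnings_noise():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
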