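import pytest
from hypothesis import settings

from cookfield.exposure_model import ModelCoefficients, load_default_coefficients

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_coefs() -> dict[int, ModelCoefficients]:
    """The packaged reference fit for all four models."""
    return load_default_coefficients()


@pytest.fixture(scope="session")
def model1_truth(default_coefs) -> ModelCoefficients:
    return default_coefs[1]
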