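import pytest

from coraldeb import ModelParameters, ThermalParams


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default model parameters (28 degree C reference table, full variant)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def thermal() -> ThermalParams:
    return ThermalParams()
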