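import pytest

from fetalfrac import build_correction_model


@pytest.fixture(scope="session")
def model65():
    """Correction model calibrated at 65-fold only (shared across tests)."""
    return build_correction_model(depths=[65], seed=101)


@pytest.fixture(scope="session")
def sweep_model():
    """Correction model calibrated at the depth-sweep grid."""
    return build_correction_model(depths=[70, 100, 130, 160, 200], seed=202)
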