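import pytest

from foldlock import DesignConfig, calibrate, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def calibration(registry):
    return calibrate(DesignConfig(), registry)


@pytest.fixture(scope="session")
def calibrated_config(calibration):
    return calibration.config
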