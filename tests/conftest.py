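import pytest

from safeward.hospital_model import BaselineParams, calibrate, load_anchor_fixture


@pytest.fixture(scope="session")
def base():
    return BaselineParams()


@pytest.fixture(scope="session")
def anchors():
    return load_anchor_fixture()


@pytest.fixture(scope="session")
def params(anchors, base):
    return calibrate(anchors, base)
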