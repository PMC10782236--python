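import pytest

from cupversion import default_pelvis_model


@pytest.fixture(scope="session")
def model():
    return default_pelvis_model()
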