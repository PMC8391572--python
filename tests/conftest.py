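import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def consts():
    from parloud.constants import default_constants

    return default_constants()
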