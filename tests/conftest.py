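import pytest

from racemap import demo_construct


@pytest.fixture(scope="session")
def construct():
    return demo_construct()
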