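import pytest

from micromle import load_case


@pytest.fixture(scope="session")
def cases():
    """The four bundled semi-quantitative case tables, keyed by number."""
    return {i: load_case(i) for i in (1, 2, 3, 4)}
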