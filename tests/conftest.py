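import pytest

from snpmeta import load_mthfr_t2dm


@pytest.fixture(scope="session")
def corpus():
    """The packaged 39-study MTHFR 677C→T / T2DM corpus."""
    return load_mthfr_t2dm()
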