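import pytest

from sbmlfeatures import FixtureSpec, generate_taxonomy


@pytest.fixture(scope="session")
def study_taxonomy():
    """The default synthetic study taxonomy (1800 concepts, binary is_a)."""
    return generate_taxonomy(FixtureSpec(seed=0))
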