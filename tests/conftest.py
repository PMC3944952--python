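import pytest

from atlasbridge import build_reference_fixture, derive_pathways


@pytest.fixture()
def onto():
    return build_reference_fixture()


@pytest.fixture()
def derived(onto):
    """Reference fixture with inferred pathway edges materialized."""
    derive_pathways(onto)
    return onto
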