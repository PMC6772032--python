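import pytest

from crossruns import SymmetricJointCache


@pytest.fixture(scope="session")
def sym_cache():
    """One symmetric-case cache shared across the whole run; the iterative
    build for length n consumes every shorter length, so sharing it makes
    the n<=200 checks cheap."""
    return SymmetricJointCache()
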