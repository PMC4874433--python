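import numpy as np
import pytest

from tissuecoal.runner import make_fixture


@pytest.fixture(scope="session")
def chain_genealogy():
    return make_fixture("chain")


@pytest.fixture(scope="session")
def star_genealogy():
    return make_fixture("star")


@pytest.fixture(scope="session")
def wf_tiny():
    return make_fixture("wf-tiny")


@pytest.fixture(scope="session")
def eden_tiny():
    return make_fixture("eden-tiny")


# golden lineage curve of the wf-tiny fixture (N=4, G=20, seed 20240917),
# generated once with the set-based brute-force traversal oracle
WF_TINY_GOLDEN = np.array(
    [4, 2] + [1] * 19, dtype=np.int64
)


@pytest.fixture(scope="session")
def wf_tiny_golden():
    return WF_TINY_GOLDEN
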