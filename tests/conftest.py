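import numpy as np
import pytest

from norevo.report import reconstruct_segments
from norevo.synthetic_data import make_study_fixture


@pytest.fixture(scope="session")
def study():
    return make_study_fixture()


@pytest.fixture(scope="session")
def study_recons(study):
    """Deterministic full-fixture reconstruction, shared across tests."""
    return reconstruct_segments(study.tree, study.matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(20110513)
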