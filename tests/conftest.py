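import numpy as np
import pytest

from ciesim.io import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Bundled small deterministic cohorts (one per family + degenerates)."""
    return make_fixtures(seed=90210)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
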