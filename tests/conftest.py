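import numpy as np
import pytest

from drseg import phantoms


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_corpus():
    """Four 32^3 phantoms with one lateral pair (3 foreground labels)."""
    rng = np.random.default_rng(7)
    corpus, pairs, roles = phantoms.make_phantom_corpus(4, (32, 32, 32), 2, rng)
    return corpus, pairs, roles


@pytest.fixture(scope="session")
def desk_config():
    return phantoms.phantom_generation_config(2)


@pytest.fixture(scope="session")
def lesion_masks():
    return phantoms.make_lesion_blobs(6, np.random.default_rng(11))
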