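import logging

import numpy as np
import pytest

from cryseg.synthetic_cry import CorpusSpec, gen_corpus

# hmmlearn logs loudly about deliberately tiny smoke models
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
logging.getLogger("hmmlearn.hmm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Five short separable recordings shared by the slower tests."""
    return gen_corpus(CorpusSpec(n_recordings=5, duration_s=6.0, seed=2))


@pytest.fixture(scope="session")
def separable_corpus():
    """The packaged reference corpus: 20 recordings x 10 s, seed 1."""
    return gen_corpus(CorpusSpec(n_recordings=20, duration_s=10.0, seed=1))
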