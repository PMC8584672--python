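import numpy as np
import pytest

from prunebm import core_bm, synthetic_data as sd


@pytest.fixture
def tiny_rbm():
    """3+2-unit RBM with moderate random weights (enumerable oracle size)."""
    return core_bm.init_rbm(3, 2, weight_sd=0.8, seed=2)


@pytest.fixture
def tiny_dbm():
    """2-2-2 DBM, enumerable."""
    return core_bm.init_dbm([2, 2, 2], weight_sd=0.7, seed=5)


@pytest.fixture
def mixture_data():
    """Small sample from the canonical prototype-mixture fixture."""
    return sd.generate_mixture(sd.patch_mixture_spec(n_samples=500, seed=7))
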