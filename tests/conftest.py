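import numpy as np
import pytest

from ampscreen import BiasModel, LocusSpec, make_synthetic_locus


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def single_cut_locus():
    """A deterministic 240 bp locus with one interior cut site."""
    return make_synthetic_locus(240, 1, seed=11, name="single")


@pytest.fixture
def triple_cut_locus():
    """A deterministic 400 bp locus with three tiled cut sites."""
    return make_synthetic_locus(400, 3, seed=12, name="triple")


@pytest.fixture
def identity_bias():
    return BiasModel.identity()


@pytest.fixture
def study_bias():
    return BiasModel.fixed()
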