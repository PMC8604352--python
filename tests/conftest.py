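import numpy as np
import pytest

from paladin.core import EnergyTermMatrix, PSSM, default_weights
from paladin.datasets import default_propensity_scales
from paladin.synthetic import FixtureSpec, gen_benchmark, gen_peptide_array, gen_pssm


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(seed=7, n_peptides=240, n_proteins=6, n_benchmark=12)


@pytest.fixture(scope="session")
def truth(small_spec):
    """(pssm, terms) of the small synthetic study."""
    return gen_pssm(small_spec)


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture(scope="session")
def scales():
    return default_propensity_scales()


@pytest.fixture(scope="session")
def array_fixture(small_spec, truth, weights):
    pssm, _ = truth
    return gen_peptide_array(small_spec, pssm, weights)


@pytest.fixture(scope="session")
def benchmark_fixture(small_spec, truth, weights):
    pssm, _ = truth
    return gen_benchmark(small_spec, pssm, weights)


def random_pssm(rng, scale=2.0):
    return PSSM(rng.normal(0.0, scale, size=(5, 20)))


def random_terms(rng, scale=1.0):
    return EnergyTermMatrix(rng.normal(0.0, scale, size=(5, 20, 6)))


def random_sequence(rng, length):
    from paladin.core import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
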