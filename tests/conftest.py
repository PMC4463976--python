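import numpy as np
import pandas as pd
import pytest

import kinherit as kh


@pytest.fixture(scope="session")
def eig138():
    """Eigen-kinship of the standard 2-family, 138-subject synthetic pedigree."""
    return kh.simulate.default_eigen()


@pytest.fixture(scope="session")
def design138():
    return kh.make_design(138)


@pytest.fixture(scope="session")
def model138(eig138, design138):
    """A moderately heritable (h2=0.4) transformed dataset on 138 subjects."""
    X, beta = design138
    y = kh.simulate_phenotype(0.4, eig138, X, beta, seed=17, domain="transformed")
    return kh.TransformedModel(Y_star=y, X_star=eig138.S.T @ X, lambda_g=eig138.lambda_g)


@pytest.fixture(scope="session")
def tiny_setup():
    """N=10 two-family pedigree with kinship, eigen, design and dense 2*Phi."""
    ped = kh.generate_pedigree(2, 10, seed=99)
    kin = kh.kinship_from_pedigree(ped)
    eig = kh.eigen_kinship(kin)
    X = np.column_stack([np.ones(10), np.linspace(-1, 1, 10)])
    return ped, kin, eig, X


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ped(rows):
    """Helper: build a PedigreeTable from (id, father, mother, family) tuples."""
    return kh.PedigreeTable(
        pd.DataFrame(rows, columns=["id", "father", "mother", "family"])
    )
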