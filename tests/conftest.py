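import numpy as np
import pandas as pd
import pytest

from resevol.codon_evolution import PhyloTree
from resevol.codons import N_SENSE
from resevol.structure_rsa import RSAProfile, _profile_frame
from resevol.synthetic_data import DEFAULT_TREE


@pytest.fixture(scope="session")
def yeast_tree() -> PhyloTree:
    return PhyloTree.from_newick(DEFAULT_TREE)


@pytest.fixture(scope="session")
def uniform_pi() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def make_rsa_profile(values, types=None) -> RSAProfile:
    values = np.asarray(values, dtype=float)
    if types is None:
        types = ["A"] * len(values)
    return RSAProfile(_profile_frame(np.arange(1, len(values) + 1), types, values))


@pytest.fixture
def rsa_profile_factory():
    return make_rsa_profile
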