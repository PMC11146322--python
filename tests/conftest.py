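import numpy as np
import pytest

from hotspotsel.io_formats import CodonAlignment, read_labeled_tree
from hotspotsel.synthetic_data import (
    SimCodonSpec,
    default_test_tree,
    simulate_codon_alignment,
)


@pytest.fixture
def quartet_tree():
    return read_labeled_tree("((A:0.10,B:0.15):0.05,(C:0.20,D:0.25):0.08);")


@pytest.fixture
def small_tree():
    return default_test_tree(8, foreground_tip="T1")


@pytest.fixture
def small_alignment(small_tree):
    spec = SimCodonSpec(small_tree, kappa=2.0, omega_background=0.2, n_codons=300, seed=7)
    return simulate_codon_alignment(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240531)


def make_alignment(seqs: dict[str, str], gene_id: str = "toy") -> CodonAlignment:
    return CodonAlignment(gene_id, tuple(seqs), {k: v.upper() for k, v in seqs.items()})


@pytest.fixture
def toy_alignment_factory():
    return make_alignment
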