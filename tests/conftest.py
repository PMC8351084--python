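import numpy as np
import pytest

from lcaroot import (
    NUCLEOTIDE,
    Alignment,
    SimulationSpec,
    jc,
    lg,
    simulate_alignment,
)
from lcaroot.tree import Tree


@pytest.fixture(scope="session")
def jc_model():
    return jc()


@pytest.fixture(scope="session")
def lg_model():
    return lg()


@pytest.fixture
def toy_alignment():
    """4 taxa x 4 columns; column 1 is the only singleton column."""
    return Alignment.from_mapping(
        {"t1": "AAAA", "t2": "ACA-", "t3": "ACTA", "t4": "ACTA"},
        NUCLEOTIDE,
    )


@pytest.fixture(scope="session")
def quartet_tree():
    return Tree.from_newick("((a:0.2,b:0.3):0.1,c:0.25,d:0.4);")


@pytest.fixture(scope="session")
def five_taxon_sim():
    """Simulated nucleotide data on a known 5-taxon tree."""
    tree = Tree.from_newick(
        "((a:0.1,b:0.15):0.1,(c:0.12,d:0.08):0.1,e:0.2);"
    )
    model = jc(gamma_shape=1.0)
    aln, root_seq = simulate_alignment(
        SimulationSpec(tree=tree, model=model, n_sites=1500, seed=11)
    )
    return tree, model, aln, root_seq


def random_alignment(rng, n_taxa, length, alphabet=NUCLEOTIDE, gap_rate=0.0):
    symbols = list(alphabet.states)
    rows = {}
    for i in range(n_taxa):
        seq = rng.choice(symbols, size=length)
        if gap_rate:
            mask = rng.random(length) < gap_rate
            seq = np.where(mask, "-", seq)
        rows[f"t{i}"] = "".join(seq)
    return Alignment.from_mapping(rows, alphabet)
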