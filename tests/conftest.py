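import numpy as np
import pytest

import phylorobust as pr


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quartet_tree():
    return pr.parse_newick("((A:1,B:1):0.5,C:1,D:1);")


def random_instance(seed, n_taxa=4, n_cols=6, k=2):
    """Small random tree + alignment + GTR model for oracle comparisons."""
    rng = np.random.default_rng(seed)
    cfg = pr.SimulationConfig(n_taxa=n_taxa, seed=seed, scale_root_to_tip=0.4)
    tree = pr.simulate_tree(cfg)
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    model = pr.SubstModel.gtr(
        rng.uniform(0.5, 2.0, 6), rng.dirichlet([5.0] * 4), alpha=0.7, k=k
    )
    data = rng.choice(list("ACGT-"), size=(n_taxa, n_cols), p=[0.24] * 4 + [0.04])
    aln = pr.Alignment(labels=labels, data=data)
    return aln, tree, model


@pytest.fixture
def small_dataset():
    cfg = pr.SimulationConfig(
        n_taxa=12,
        n_sites_dna=300,
        n_sites_protein=0,
        model_protein=None,
        long_branch_spec=(0, 1.0),
        rogue_spec=(0, 1.0),
        seed=5,
    )
    return pr.make_dataset(cfg)
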