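import numpy as np
import pytest
from hypothesis import settings

from phylotier.seqdata import PartitionedAlignment
from phylotier.substmodels import SubstitutionModel
from phylotier.trees import Tree

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture
def jc():
    return SubstitutionModel.jc()


@pytest.fixture
def quartet_tree():
    return Tree.from_newick("((A:0.1,B:0.15):0.05,(C:0.12,D:0.08):0.07);")


@pytest.fixture
def quartet_aln():
    from phylotier.synthetic import simulate_alignment

    tree = Tree.from_newick("((A:0.1,B:0.15):0.05,(C:0.12,D:0.08):0.07);")
    return simulate_alignment(tree, SubstitutionModel.jc(gamma_shape=0.5), 300, 11)


@pytest.fixture(scope="session")
def reference_study():
    """One cached default synthetic study used by several test modules."""
    from phylotier.synthetic import default_study_config, make_placement_study

    cfg = default_study_config(5)
    backbone, aln, truth = make_placement_study(cfg)
    return cfg, backbone, aln, truth


def random_trees(n_trees, n_leaves, seed, blr=(0.05, 0.2)):
    from phylotier.synthetic import random_tree

    rng = np.random.default_rng(seed)
    return [random_tree(n_leaves, rng, blr) for _ in range(n_trees)]
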