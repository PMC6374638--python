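import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from laccevo.polyporales import build_gene_tree, build_species_tree, fixture_synteny
from laccevo.trees import Tree, TreeNode

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=50,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def species_tree():
    return build_species_tree()


@pytest.fixture(scope="session")
def gene_tree(species_tree):
    return build_gene_tree(species_tree)


@pytest.fixture(scope="session")
def synteny(gene_tree):
    return fixture_synteny(gene_tree)


def random_tree(seed, labels, lengths=True, supports=False) -> Tree:
    """Random rooted binary tree built by stepwise leaf insertion."""
    rng = np.random.default_rng(seed)
    labels = list(labels)
    assert len(labels) >= 2

    def leaf(lbl):
        n = TreeNode(label=lbl)
        if lengths:
            n.length = round(float(rng.uniform(0.05, 2.0)), 4)
        return n

    root = TreeNode()
    root.add_child(leaf(labels[0]))
    root.add_child(leaf(labels[1]))
    for lbl in labels[2:]:
        edges = [n for n in root.postorder() if not n.is_root]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = TreeNode()
        if lengths:
            mid.length = round(float(rng.uniform(0.05, 2.0)), 4)
        if supports:
            mid.support = round(float(rng.uniform(0, 100)), 1)
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(leaf(lbl))
    return Tree(root)
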