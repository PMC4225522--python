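import numpy as np
import pytest

from dtlcoev import DatedSpeciesTree, GeneTree, yule_tree


@pytest.fixture
def three_taxon_tree():
    return DatedSpeciesTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_taxon_tree():
    return DatedSpeciesTree.from_newick("(A:1,B:1);")


def random_species_tree(rng, n_leaves, height=10.0):
    return yule_tree(n_leaves, height, rng)


def random_gene_tree(rng, species_tree, n_leaves):
    """Random binary topology whose leaves pick species uniformly."""
    labels = [species_tree.labels[i] for i in species_tree.leaves]
    tips = [(None,)] * n_leaves  # placeholder leaves
    nodes = [("leaf", i) for i in range(n_leaves)]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        nodes.append(("int", a, b))
    children, parent, labs, species = [], [], [], []

    def build(nd):
        if nd[0] == "leaf":
            idx = len(children)
            children.append(())
            parent.append(-1)
            sp = labels[int(rng.integers(0, len(labels)))]
            labs.append(f"{sp}_{nd[1]}")
            species.append(sp)
            return idx
        ia = build(nd[1])
        ib = build(nd[2])
        idx = len(children)
        children.append((ia, ib))
        parent.append(-1)
        labs.append(None)
        species.append(None)
        parent[ia] = idx
        parent[ib] = idx
        return idx

    build(nodes[0])
    return GeneTree(children, parent, labs, species)
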