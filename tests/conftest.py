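import numpy as np
import pytest
from hypothesis import settings

from phylogrid.grids import GridSpec
from phylogrid.rasterops import PresenceAbsenceMatrix
from phylogrid.trees import parse_newick

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def micro_tree():
    """Three-tip tree used throughout: ((A:1,B:1):1,C:2); total length 5."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def micro_pam():
    """Two cells: cell 0 holds {A, B}, cell 1 holds {C}."""
    grid = GridSpec(x_origin=0.0, y_origin=2.0, cell_size=1.0, n_rows=1, n_cols=2)
    return PresenceAbsenceMatrix(
        matrix=np.array([[1, 1, 0], [0, 0, 1]]),
        species=["A", "B", "C"],
        rows=[0, 0],
        cols=[0, 1],
        grid=grid,
    )


def random_pam(rng, n_cells, n_species, grid=None, p=0.4):
    """A random PAM with no empty species and no empty cells."""
    while True:
        m = (rng.random((n_cells, n_species)) < p).astype(np.uint8)
        if m.sum(axis=0).min() >= 1 and m.sum(axis=1).min() >= 1:
            break
    if grid is None:
        grid = GridSpec(0.0, float(n_cells), 1.0, n_cells, 1)
    return PresenceAbsenceMatrix(
        matrix=m,
        species=[f"s{i}" for i in range(n_species)],
        rows=np.arange(n_cells),
        cols=np.zeros(n_cells, dtype=int),
        grid=grid,
    )


def random_ultrametric_tree(rng, labels):
    """Random coalescent-style ultrametric tree over the given tip labels."""
    nodes = [(lab, 0.0) for lab in labels]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.exponential(1.0)) + 0.1
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{height - ha},{nb}:{height - hb})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append((merged, height))
    return parse_newick(nodes[0][0] + ";")


def brute_force_pd(tree, tip_set):
    """Independent PD oracle: walk each tip to the root, union the edges."""
    edges = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in tip_set:
            continue
        node = leaf
        while node.parent_node is not None:
            edges[id(node)] = node.edge.length or 0.0
            node = node.parent_node
    return sum(edges.values())


def brute_force_pe(tree, pam):
    """Independent PE oracle: explicit branch-range bookkeeping per cell."""
    cells = [
        {s for s, v in zip(pam.species, row) if v} for row in pam.matrix
    ]
    # branch -> list of (length, set of descendant tips)
    branches = []
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        tips = {l.taxon.label for l in node.leaf_iter()}
        branches.append((node.edge.length or 0.0, tips))
    L_tot = sum(l for l, _ in branches)
    out = []
    for cell in cells:
        total = 0.0
        for length, tips in branches:
            if tips & cell:
                r = sum(1 for other in cells if tips & other)
                total += length / r
        out.append(total / L_tot)
    return np.array(out)
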