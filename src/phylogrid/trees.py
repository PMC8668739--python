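"""Tree utilities shared by the diversity and turnover layers.

Trees are dendropy ``Tree`` objects throughout: rooted, with branch lengths
in millions of years.  The central derived object is the branch-by-species
incidence matrix, from which Faith PD, Rosauer PE and the PhyloSor family
are all linear-algebra one-liners.
"""

from __future__ import annotations

import dendropy
import numpy as np

__all__ = [
    "read_tree",
    "parse_newick",
    "branch_incidence",
    "branch_lengths",
    "total_length",
    "equalize_branches",
    "prune_to_taxa",
    "is_ultrametric",
    "tree_depth",
]


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a rooted newick string with branch lengths."""
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    _check_lengths(tree)
    return tree


def read_tree(path) -> dendropy.Tree:
    """Read a rooted newick tree file; every non-root branch needs a length."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
    _check_lengths(tree)
    return tree


def _check_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            head = edge.head_node.taxon
            name = head.label if head is not None else "an internal node"
            raise ValueError(f"branch leading to {name} has no length")
        if edge.length < 0:
            raise ValueError("negative branch length")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def branch_incidence(
    tree: dendropy.Tree, species: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Branch x species incidence and branch lengths.

    Returns ``(B, L)`` where ``B[b, i]`` is True iff branch ``b`` lies on the
    path from tip ``species[i]`` to the root, and ``L[b]`` its length.  The
    root's own edge is excluded.  Species missing from the tree raise.
    """
    index = {label: i for i, label in enumerate(species)}
    seen = set()
    rows = []
    lengths = []
    # postorder: each edge's descendant-tip set is the union of its children's
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        mask = np.zeros(len(species), dtype=bool)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label in index:
                mask[index[label]] = True
            if label is not None:
                seen.add(label)
        else:
            for child in node.child_nodes():
                mask |= below[id(child)]
        below[id(node)] = mask
        if node.parent_node is not None:
            rows.append(mask)
            lengths.append(node.edge.length or 0.0)
    missing = set(species) - seen
    if missing:
        raise KeyError(f"species not found as tree tips: {sorted(missing)}")
    return np.array(rows, dtype=bool), np.array(lengths, dtype=float)


def branch_lengths(tree: dendropy.Tree) -> np.ndarray:
    return np.array(
        [e.length or 0.0 for e in tree.preorder_edge_iter() if e.tail_node is not None]
    )


def total_length(tree: dendropy.Tree) -> float:
    """Sum of all non-root branch lengths."""
    return float(branch_lengths(tree).sum())


def equalize_branches(tree: dendropy.Tree) -> dendropy.Tree:
    """Same topology with every branch length set to 1.

    Any common constant cancels in the tree-length-scaled PD/PE ratios, so
    unit lengths and equal-total-length rescaling give identical RPD/RPE.
    """
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = 1.0
    return out


def prune_to_taxa(tree: dendropy.Tree, keep: list[str]) -> dendropy.Tree:
    """Prune the tree to the given tip labels (copy; original untouched)."""
    out = tree.clone(depth=1)
    taxa = [t for t in out.taxon_namespace if t.label in set(keep)]
    if not taxa:
        raise ValueError("no requested taxa found in tree")
    out.retain_taxa(taxa)
    return out


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip distance."""
    return float(max(leaf.distance_from_root() for leaf in tree.leaf_node_iter()))


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = np.array([leaf.distance_from_root() for leaf in tree.leaf_node_iter()])
    depth = depths.max()
    if depth == 0:
        return True
    return bool(np.all(np.abs(depths - depth) <= rel_tol * depth))
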