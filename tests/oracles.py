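"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's fast paths: they walk dendropy node
objects directly and enumerate every internal node.
"""
from __future__ import annotations

import dendropy
import numpy as np


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def node_tip_distance(node: dendropy.Node, leaf: dendropy.Node) -> float:
    """Branch-length distance from ``node`` down to ``leaf``."""
    d = 0.0
    cur = leaf
    while cur is not node:
        d += cur.edge.length or 0.0
        cur = cur.parent_node
    return d


def brute_positive_clades(
    tree: dendropy.Tree, trait: dict[str, bool], min_fraction: float
) -> tuple[list[frozenset[str]], list[str]]:
    """All maximal positive clades (tip-label sets) and positive singletons.

    Scans every internal node; a node qualifies if >= 2 tips and its positive
    fraction reaches the threshold; maximality = no qualifying ancestor.
    """
    qualifying = []
    for node in tree.preorder_node_iter():
        leaves = list(node.leaf_iter())
        if len(leaves) < 2:
            continue
        pos = sum(bool(trait[l.taxon.label]) for l in leaves)
        if pos / len(leaves) >= min_fraction:
            qualifying.append(node)
    maximal = []
    for node in qualifying:
        anc = node.parent_node
        has_anc = False
        while anc is not None:
            if anc in qualifying:
                has_anc = True
                break
            anc = anc.parent_node
        if not has_anc:
            maximal.append(node)
    clade_sets = [
        frozenset(l.taxon.label for l in node.leaf_iter()) for node in maximal
    ]
    covered = set().union(*clade_sets) if clade_sets else set()
    singletons = [
        l.taxon.label
        for l in tree.leaf_node_iter()
        if trait[l.taxon.label] and l.taxon.label not in covered
    ]
    return clade_sets, singletons


def brute_tau(
    tree: dendropy.Tree,
    trait: dict[str, bool],
    min_fraction: float,
    singleton_factor: float,
) -> float:
    """tau_D by direct recomputation from the maximal clades."""
    clade_sets, singletons = brute_positive_clades(tree, trait, min_fraction)
    label_to_leaf = {l.taxon.label: l for l in tree.leaf_node_iter()}
    depths = []
    for cs in clade_sets:
        node = tree.mrca(taxon_labels=sorted(cs))
        leaves = list(node.leaf_iter())
        depths.append(np.mean([node_tip_distance(node, l) for l in leaves]))
    for s in singletons:
        depths.append(singleton_factor * (label_to_leaf[s].edge.length or 0.0))
    return float(np.mean(depths))


def brute_abouheif_proximity(tree: dendropy.Tree) -> np.ndarray:
    """Abouheif proximity by literal path enumeration through the root."""
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            anc_i = list(leaves[i].ancestor_iter())
            anc_j = list(leaves[j].ancestor_iter())
            path = {id(x): x for x in anc_i + anc_j}
            prod = 1.0
            for node in path.values():
                prod *= len(node.child_nodes())
            a[i, j] = 1.0 / prod
    return a


def brute_cmean(tree: dendropy.Tree, x: np.ndarray) -> float:
    """Moran autocorrelation under the row-normalized Abouheif matrix, by loops."""
    a = brute_abouheif_proximity(tree)
    w = a / a.sum(axis=1, keepdims=True)
    xc = x - x.mean()
    num = 0.0
    for i in range(len(x)):
        for j in range(len(x)):
            num += w[i, j] * xc[i] * xc[j]
    return num / (xc @ xc)


def random_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random binary topology with uniform branch lengths, built by pair joins."""
    parts = [f"T{i}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        la, lb = rng.uniform(0.05, 1.0, size=2)
        parts.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    t = dendropy.Tree.get(data=parts[0] + ";", schema="newick",
                          preserve_underscores=True)
    t.is_rooted = True
    return t
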