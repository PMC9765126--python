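"""Phylogenetic conservation of binary carbohydrate-utilization traits.

Two statistics are provided, each with a tip-label permutation null:

* **Abouheif's Cmean** — a Moran-type autocorrelation of a (centered) trait
  under a phylogenetic proximity matrix built from the number of direct
  descendants of the internal nodes connecting two tips (the path always
  passes through the root).  Sensitive to any phylogenetic signal.

* **consenTRAIT trait depth (tau_D)** — identifies the maximal clades whose
  tips are (almost) all trait-positive and averages the branch-length depth of
  those clades; deep clades mean the trait is conserved across relatives.
  On 16S trees tau_D is in substitutions/site, and ``identity = 1 - 2 * tau_D``
  converts it into the familiar 16S sequence-identity scale (divergence in
  percent is ``200 * tau_D``).
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GenomeMetadata

__all__ = [
    "TreeIndex",
    "Clade",
    "CmeanResult",
    "ConsenTraitResult",
    "filter_for_phylogeny",
    "abouheif_proximity",
    "cmean",
    "find_positive_clades",
    "tau_D",
    "permutation_test_tau",
    "identity_from_tau",
    "run_conservation_suite",
]


class TreeIndex:
    """Immutable array view of a rooted dendropy tree for fast trait scans.

    Nodes are indexed in preorder; for each node the index caches its children,
    the tips below it, and the mean branch-length distance from the node down
    to those tips.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        nodes = list(tree.preorder_node_iter())
        self.n_nodes = len(nodes)
        index_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.edge_length = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.is_leaf = np.zeros(self.n_nodes, dtype=bool)
        leaf_nodes = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index_of[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.edge_length[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                self.is_leaf[i] = True
                leaf_nodes.append(i)
        self.tip_labels = [nodes[i].taxon.label for i in leaf_nodes]
        self.n_tips = len(leaf_nodes)
        self.tip_of_node = np.full(self.n_nodes, -1, dtype=int)
        for t, i in enumerate(leaf_nodes):
            self.tip_of_node[i] = t
        # postorder = reversed preorder works for child-before-parent sweeps
        self.postorder = np.arange(self.n_nodes)[::-1]
        self.n_tips_below = np.zeros(self.n_nodes, dtype=int)
        sum_depth = np.zeros(self.n_nodes)
        tips_below: list[np.ndarray] = [np.empty(0, dtype=int)] * self.n_nodes
        for i in self.postorder:
            if self.is_leaf[i]:
                self.n_tips_below[i] = 1
                tips_below[i] = np.array([self.tip_of_node[i]], dtype=int)
            else:
                kids = self.children[i]
                self.n_tips_below[i] = sum(self.n_tips_below[k] for k in kids)
                sum_depth[i] = sum(
                    sum_depth[k] + self.edge_length[k] * self.n_tips_below[k]
                    for k in kids
                )
                tips_below[i] = np.concatenate([tips_below[k] for k in kids])
        self.tips_below = tips_below
        self.mean_depth = sum_depth / self.n_tips_below
        self.terminal_length = np.zeros(self.n_tips)
        for i in leaf_nodes:
            self.terminal_length[self.tip_of_node[i]] = self.edge_length[i]
        self._leaf_node_index = np.array(leaf_nodes, dtype=int)

    @property
    def root_mean_depth(self) -> float:
        """Mean root-to-tip branch-length distance."""
        return float(self.mean_depth[0])

    def trait_vector(self, trait: Mapping[str, bool] | Sequence[bool]) -> np.ndarray:
        """Align a tip -> value mapping (or tip-ordered sequence) to the index."""
        if isinstance(trait, Mapping):
            missing = [l for l in self.tip_labels if l not in trait]
            if missing:
                raise ValueError(f"trait missing tips: {missing[:5]}")
            return np.array([trait[l] for l in self.tip_labels], dtype=float)
        v = np.asarray(trait, dtype=float)
        if v.size != self.n_tips:
            raise ValueError("trait length does not match number of tips")
        return v

    def positive_counts(self, x: np.ndarray) -> np.ndarray:
        """Number of positive tips below every node (postorder accumulation)."""
        counts = np.zeros(self.n_nodes)
        counts[self._leaf_node_index] = x
        for i in self.postorder:
            p = self.parent[i]
            if p >= 0:
                counts[p] += counts[i]
        return counts


def _as_index(tree: dendropy.Tree | TreeIndex) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex(tree)


def filter_for_phylogeny(metadata: Iterable[GenomeMetadata]) -> list[str]:
    """Genomes usable on 16S trees: high quality with exactly one 16S copy."""
    return [
        m.genome_id
        for m in metadata
        if m.quality == "high" and m.n_16S_copies == 1
    ]


# ---------------------------------------------------------------------------
# Abouheif's Cmean
# ---------------------------------------------------------------------------

def abouheif_proximity(tree: dendropy.Tree | TreeIndex) -> pd.DataFrame:
    """Abouheif phylogenetic proximity between tips.

    For tips i != j the proximity is 1 over the product of the number of direct
    descendants of every internal node on the path connecting them through the
    root (shared ancestors counted once); the diagonal is zero.  On a star tree
    with k tips every off-diagonal entry is 1/k; tips of a cherry under a
    binary root get 1/4.
    """
    idx = _as_index(tree)
    dd = np.array([len(c) for c in idx.children], dtype=float)
    # path of ancestor nodes (internal) from root for each tip, and the product
    # of dd over each tip's ancestors
    anc_path: list[list[int]] = []
    prod_anc = np.ones(idx.n_tips)
    for node, t in zip(idx._leaf_node_index, range(idx.n_tips)):
        path = []
        p = idx.parent[node]
        while p >= 0:
            path.append(p)
            p = idx.parent[p]
        path = path[::-1]  # root first
        anc_path.append(path)
        prod_anc[t] = np.prod(dd[path])
    # product of dd over a node and all its ancestors
    prod_to_root = np.ones(idx.n_nodes)
    for i in range(idx.n_nodes):
        p = idx.parent[i]
        prod_to_root[i] = dd[i] * (prod_to_root[p] if p >= 0 else 1.0)
    a = np.zeros((idx.n_tips, idx.n_tips))
    for i in range(idx.n_tips):
        for jj in range(i + 1, idx.n_tips):
            pi, pj = anc_path[i], anc_path[jj]
            k = 0
            m = min(len(pi), len(pj))
            while k < m and pi[k] == pj[k]:
                k += 1
            mrca = pi[k - 1]  # paths share the root, k >= 1
            val = prod_to_root[mrca] / (prod_anc[i] * prod_anc[jj])
            a[i, jj] = a[jj, i] = val
    return pd.DataFrame(a, index=idx.tip_labels, columns=idx.tip_labels)


@dataclasses.dataclass
class CmeanResult:
    cmean: float
    p_value: float
    n_permutations: int


def _moran(x: np.ndarray, w: np.ndarray) -> float:
    xc = x - x.mean()
    denom = xc @ xc
    return float(xc @ w @ xc / denom)


def cmean(
    tree: dendropy.Tree | TreeIndex,
    trait: Mapping[str, bool] | Sequence[float],
    n_perm: int = 999,
    seed: int | np.random.SeedSequence | None = 0,
    proximity: np.ndarray | None = None,
) -> CmeanResult:
    """Abouheif's Cmean with a tip-label permutation test.

    The statistic is the Moran autocorrelation of the centered trait under the
    row-normalized Abouheif proximity matrix.  Works for binary presence/
    absence traits as well as quantitative ones (e.g. gene counts per genome).
    p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    idx = _as_index(tree)
    x = idx.trait_vector(trait)
    if np.allclose(x, x[0]):
        raise ValueError("no variance: trait is constant across tips")
    if proximity is None:
        proximity = abouheif_proximity(idx).to_numpy()
    w = proximity / proximity.sum(axis=1, keepdims=True)
    obs = _moran(x, w)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        if _moran(x[rng.permutation(x.size)], w) >= obs:
            ge += 1
    return CmeanResult(cmean=obs, p_value=(1 + ge) / (1 + n_perm), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# consenTRAIT
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Clade:
    """A trait-positive clade (or positive singleton tip)."""

    node_id: int
    tip_labels: tuple[str, ...]
    n_tips: int
    n_positive: int
    depth: float
    is_singleton: bool = False


def find_positive_clades(
    tree: dendropy.Tree | TreeIndex,
    trait: Mapping[str, bool] | Sequence[bool],
    min_fraction: float = 0.90,
) -> list[Clade]:
    """Maximal clades whose positive-tip fraction reaches ``min_fraction``.

    Returns non-nested clades with at least two tips, plus positive singleton
    tips not contained in any such clade (``is_singleton`` set; their depth is
    the terminal branch length, weighted later by the singleton factor).
    """
    idx = _as_index(tree)
    x = idx.trait_vector(trait)
    counts = idx.positive_counts(x)
    out: list[Clade] = []
    stack = [0]
    while stack:
        i = stack.pop()
        if counts[i] == 0:
            continue
        n = idx.n_tips_below[i]
        if n >= 2 and counts[i] / n >= min_fraction:
            tips = idx.tips_below[i]
            out.append(
                Clade(
                    node_id=i,
                    tip_labels=tuple(idx.tip_labels[t] for t in tips),
                    n_tips=int(n),
                    n_positive=int(counts[i]),
                    depth=float(idx.mean_depth[i]),
                )
            )
        elif idx.is_leaf[i]:
            t = idx.tip_of_node[i]
            out.append(
                Clade(
                    node_id=i,
                    tip_labels=(idx.tip_labels[t],),
                    n_tips=1,
                    n_positive=1,
                    depth=float(idx.terminal_length[t]),
                    is_singleton=True,
                )
            )
        else:
            stack.extend(idx.children[i])
    return out


@dataclasses.dataclass
class ConsenTraitResult:
    """Mean trait depth and its permutation significance.

    ``identity`` is the 16S sequence-identity equivalent ``1 - 2 * tau_D`` and
    ``divergence_pct`` is ``200 * tau_D`` (percent sequence divergence spanned
    by the positive clades).
    """

    tau_D: float
    n_positive_clades: int
    n_singletons: int
    p_value: float | None
    n_permutations: int
    identity: float
    divergence_pct: float


def _tau_from_counts(idx: TreeIndex, counts: np.ndarray, x: np.ndarray,
                     min_fraction: float, singleton_factor: float) -> float:
    """Fast tau_D: mean clade depth over maximal positive clades + singletons."""
    total = 0.0
    k = 0
    stack = [0]
    while stack:
        i = stack.pop()
        if counts[i] == 0:
            continue
        n = idx.n_tips_below[i]
        if n >= 2 and counts[i] / n >= min_fraction:
            total += idx.mean_depth[i]
            k += 1
        elif idx.is_leaf[i]:
            total += singleton_factor * idx.terminal_length[idx.tip_of_node[i]]
            k += 1
        else:
            stack.extend(idx.children[i])
    return total / k


def tau_D(
    tree: dendropy.Tree | TreeIndex,
    trait: Mapping[str, bool] | Sequence[bool],
    min_fraction: float = 0.90,
    singleton_factor: float = 0.5,
) -> ConsenTraitResult:
    """Mean phylogenetic depth of the trait-positive clades (no p-value yet).

    The depth of a clade is the mean branch-length distance from its ancestral
    node to its member tips; a positive singleton tip contributes
    ``singleton_factor`` times its terminal branch length.  tau_D is the
    unweighted mean over clades and singletons.
    """
    idx = _as_index(tree)
    x = idx.trait_vector(trait)
    if x.sum() == 0:
        raise ValueError("tau_D undefined: no positive tips")
    clades = find_positive_clades(idx, x, min_fraction=min_fraction)
    depths = [
        singleton_factor * c.depth if c.is_singleton else c.depth for c in clades
    ]
    tau = float(np.mean(depths))
    identity, divergence = identity_from_tau(tau)
    return ConsenTraitResult(
        tau_D=tau,
        n_positive_clades=sum(not c.is_singleton for c in clades),
        n_singletons=sum(c.is_singleton for c in clades),
        p_value=None,
        n_permutations=0,
        identity=identity,
        divergence_pct=divergence,
    )


def permutation_test_tau(
    tree: dendropy.Tree | TreeIndex,
    trait: Mapping[str, bool] | Sequence[bool],
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    min_fraction: float = 0.90,
    singleton_factor: float = 0.5,
    plus_one: bool = False,
) -> ConsenTraitResult:
    """consenTRAIT randomization test of trait depth.

    The trait labels are shuffled among the tips (the number of positive tips
    is preserved) ``n_perm`` times and the p-value is the fraction of permuted
    tau_D values greater than or equal to the observed one.  That literal
    fraction can be zero; ``plus_one=True`` switches to the
    (1 + #ge) / (1 + n_perm) convention.
    """
    idx = _as_index(tree)
    x = idx.trait_vector(trait)
    res = tau_D(idx, x, min_fraction=min_fraction, singleton_factor=singleton_factor)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(x.size)]
        tau_p = _tau_from_counts(
            idx, idx.positive_counts(xp), xp, min_fraction, singleton_factor
        )
        if tau_p >= res.tau_D:
            ge += 1
    p = (1 + ge) / (1 + n_perm) if plus_one else ge / n_perm
    return dataclasses.replace(res, p_value=p, n_permutations=n_perm)


def identity_from_tau(tau: float) -> tuple[float, float]:
    """Convert tau_D (substitutions/site) to 16S identity and percent divergence.

    identity = 1 - 2 * tau_D, divergence_pct = 200 * tau_D.  Values outside the
    [0, 1] identity range are returned as computed (the caller may flag them).
    """
    return 1.0 - 2.0 * tau, 200.0 * tau


def run_conservation_suite(
    trees: Mapping[str, dendropy.Tree | TreeIndex],
    traits: pd.DataFrame,
    min_tips: int = 21,
    min_fraction: float = 0.90,
    singleton_factor: float = 0.5,
    n_perm: int = 1000,
    seed: int = 0,
    keep_genomes: Sequence[str] | None = None,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per phylum x activity: tau_D, its permutation p, identity, and Cmean.

    Trees are pruned to tips present in the trait matrix (and ``keep_genomes``
    when given, e.g. the 16S single-copy filter).  Phyla with fewer than
    ``min_tips`` usable tips are skipped with a reason; constant traits (no
    positives, or all positive leaving Cmean undefined) carry status flags.
    When ``counts`` is given, Cmean is computed on per-genome gene counts per
    activity instead of the binary presence/absence trait.
    """
    keep = set(traits.index) if keep_genomes is None else set(keep_genomes) & set(traits.index)
    seeds = iter(np.random.SeedSequence(seed).spawn(len(trees) * len(traits.columns) * 2))
    rows = []
    for phylum in sorted(trees):
        tree = trees[phylum]
        base_idx = _as_index(tree)
        tips = [l for l in base_idx.tip_labels if l in keep]
        if len(tips) < min_tips:
            rows.append(
                {"phylum": phylum, "activity": None, "n_tips": len(tips),
                 "status": f"skipped: fewer than {min_tips} usable tips"}
            )
            # keep the seed stream aligned across runs with different inputs
            for _ in range(len(traits.columns) * 2):
                next(seeds)
            continue
        if len(tips) < base_idx.n_tips:
            pruned = base_idx.tree.extract_tree_with_taxa_labels(tips)
            idx = TreeIndex(pruned)
        else:
            idx = base_idx
        prox = abouheif_proximity(idx).to_numpy()
        for activity in traits.columns:
            tau_seed, cmean_seed = next(seeds), next(seeds)
            trait = traits.loc[idx.tip_labels, activity].astype(bool)
            n_pos = int(trait.sum())
            row = {
                "phylum": phylum, "activity": activity,
                "n_tips": idx.n_tips, "n_positive": n_pos,
            }
            if n_pos == 0:
                row["status"] = "no positive tips"
                rows.append(row)
                continue
            res = permutation_test_tau(
                idx, trait.to_dict(), n_perm=n_perm, seed=tau_seed,
                min_fraction=min_fraction, singleton_factor=singleton_factor,
            )
            row.update(
                tau_D=res.tau_D, p_value=res.p_value,
                identity=res.identity, divergence_pct=res.divergence_pct,
                n_positive_clades=res.n_positive_clades,
                n_singletons=res.n_singletons,
            )
            if counts is not None:
                cvec = counts.reindex(index=idx.tip_labels, fill_value=0)[activity] \
                    if activity in counts.columns else None
                cm_input = cvec.to_numpy(dtype=float) if cvec is not None else None
            else:
                cm_input = trait.to_numpy(dtype=float)
            status = "ok"
            if cm_input is None or np.allclose(cm_input, cm_input[0]):
                row["cmean"] = np.nan
                row["cmean_p"] = np.nan
                status = "constant trait: Cmean undefined" if n_pos == idx.n_tips else status
            else:
                cres = cmean(idx, cm_input, n_perm=n_perm, seed=cmean_seed,
                             proximity=prox)
                row["cmean"] = cres.cmean
                row["cmean_p"] = cres.p_value
            row["status"] = status
            rows.append(row)
    return pd.DataFrame(rows)
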