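"""Multivariate structure of genome feature tables.

Counts are filtered to abundant families, each genome's row is scaled to unit
sum of squares (so Euclidean distance becomes the chord distance, bounded by
sqrt(2) for non-negative profiles), embedded by classical metric scaling
(principal coordinates), and group effects are tested by one-factor PERMANOVA
with a seeded label-permutation null.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_abundant_families",
    "normalize_rows",
    "euclidean_distances",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "group_centroids",
    "PcoaResult",
    "PermanovaResult",
]


def filter_abundant_families(
    counts: pd.DataFrame, min_share: float = 0.001
) -> pd.DataFrame:
    """Keep family columns whose global count share strictly exceeds ``min_share``.

    The share is computed once on the full table, before any group subsetting.
    """
    total = counts.to_numpy().sum()
    if total == 0:
        raise ValueError("count matrix is empty")
    share = counts.sum(axis=0) / total
    return counts.loc[:, share > min_share]


def normalize_rows(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each genome's row to unit sum of squares (Euclidean norm one)."""
    x = counts.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = ", ".join(str(counts.index[i]) for i in zero[:5])
        raise ValueError(f"cannot normalize all-zero rows (genomes: {names})")
    return pd.DataFrame(x / norms[:, None], index=counts.index, columns=counts.columns)


def euclidean_distances(m: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between rows as a labelled distance matrix."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(m.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in m.index])


@dataclasses.dataclass
class PcoaResult:
    """Principal-coordinates embedding.

    ``eigenvalues`` holds the full descending spectrum including any negative
    eigenvalues (reported, their axes dropped); ``coordinates`` spans only the
    positive axes; ``proportion_explained`` is relative to the positive part.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, eps: float = 1e-12) -> PcoaResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix and
    returns coordinates on axes with positive eigenvalues, ordered descending.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0)
    keep = evals > eps * scale
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    pos_sum = evals[keep].sum()
    prop = evals[keep] / pos_sum if pos_sum > 0 else evals[keep]
    axes = [f"PC{i + 1}" for i in range(int(keep.sum()))]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclasses.dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def _group_masks(labels: np.ndarray) -> list[np.ndarray]:
    return [labels == g for g in np.unique(labels)]


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, ss_total: float) -> tuple[float, float]:
    n = d2.shape[0]
    ss_within = 0.0
    groups = _group_masks(labels)
    for mask in groups:
        idx = np.flatnonzero(mask)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2 * idx.size)
    a = len(groups)
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 999,
    seed: int | np.random.SeedSequence | None = 0,
) -> PermanovaResult:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic partitions the total sum of squared distances into
    among- and within-group parts; the null is built by shuffling group labels
    ``n_perm`` times and p = (1 + #{permuted F >= observed F}) / (1 + n_perm).
    """
    ids = list(dm.ids)
    if isinstance(groups, (Mapping, pd.Series)):
        labels = np.asarray([groups[i] for i in ids])
    else:
        labels = np.asarray(list(groups))
        if labels.size != len(ids):
            raise ValueError("groups length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        bad = ", ".join(uniq[counts < 2])
        raise ValueError(f"groups with fewer than two members: {bad}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    f_obs, r2 = _pseudo_f(d2, labels, ss_total)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, labels[rng.permutation(n)], ss_total)
        if f_perm >= f_obs:
            ge += 1
    return PermanovaResult(
        pseudo_F=f_obs,
        R2=r2,
        p_value=(1 + ge) / (1 + n_perm),
        n_permutations=n_perm,
    )


_CORRECTIONS = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """PERMANOVA for every unordered pair of groups, with multiplicity correction."""
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    ids = list(dm.ids)
    labels = pd.Series([groups[i] for i in ids], index=ids)
    pairs = list(itertools.combinations(sorted(labels.unique()), 2))
    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (ga, gb), ss in zip(pairs, seeds):
        keep = [i for i in ids if labels[i] in (ga, gb)]
        sub = dm.filter(keep)
        res = permanova(sub, labels.loc[keep], n_perm=n_perm, seed=ss)
        rows.append(
            {"group_a": ga, "group_b": gb, "F": res.pseudo_F, "p_raw": res.p_value}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=_CORRECTIONS[correction])[1]
    return out


def group_centroids(
    coordinates: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Group centroid coordinates per ordination axis."""
    labels = pd.Series([groups[i] for i in coordinates.index], index=coordinates.index)
    return coordinates.groupby(labels).mean()
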