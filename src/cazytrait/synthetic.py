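"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a catalog of metagenome-assembled genomes: genomes
grouped into phyla and habitats, phylum-specific CAZy family count profiles
with habitat tilts, per-phylum phylogenies, binary traits painted onto clades
of known depth (ground truth for trait-depth recovery), and raw per-gene
annotation rows with a realistic E-value spread around the filtering
threshold.  Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import (
    ActivityMap,
    GenomeMetadata,
    UNASSIGNED,
    default_activity_map,
    write_metadata,
    write_tree,
)
from .conservation import TreeIndex

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "paint_trait",
    "PaintedTrait",
    "simulate_counts",
    "write_raw_annotations",
    "generate_trees",
    "generate_dataset",
]

_HABITAT_POOL = (
    "soil", "plant-associated", "freshwater", "marine", "human-gut",
    "engineered", "sediment", "rumen", "deep-subsurface", "nonmarine-saline",
)


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic catalog.

    Defaults are chosen to resemble a down-scaled MAG catalog: tens of genomes
    per phylum, ~80 CAZyme genes per genome spread over a couple hundred
    families, 16S single-copy status for ~78% of genomes, and E-values
    log-uniform across the annotation-confidence threshold.
    """

    n_phyla: int = 10
    genomes_per_phylum: int = 50
    n_habitats: int = 6
    n_families: int = 200
    phylum_profile_concentration: float = 1.0
    habitat_effect_size: float = 0.5
    habitat_affected_fraction: float = 0.15
    mean_cazymes_per_genome: float = 80.0
    p_16s_single: float = 0.78
    p_16s_missing: float = 0.19
    evalue_pass_fraction: float = 0.8
    evalue_range: tuple[float, float] = (1e-40, 1e-5)
    signal_peptide_fraction: float = 0.2
    confound_habitat: bool = False
    tree_mean_depth: float = 0.10
    tree_model: str = "yule"
    p_in: float = 1.0
    p_out: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_16s_single, self.p_16s_missing, self.evalue_pass_fraction,
                  self.signal_peptide_fraction, self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if min(self.n_phyla, self.genomes_per_phylum, self.n_habitats,
               self.n_families) <= 0:
            raise ValueError("all counts must be positive")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _newick(children: list, lengths: np.ndarray, labels: list[str], node: int) -> str:
    if not children[node]:
        return f"{labels[node]}:{lengths[node]:.10g}"
    inner = ",".join(_newick(children, lengths, labels, c) for c in children[node])
    return f"({inner}):{lengths[node]:.10g}"


def simulate_tree(
    n_tips: int,
    model: str = "yule",
    seed: int | np.random.SeedSequence | None = 0,
    mean_depth: float = 0.10,
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Simulate a rooted binary tree with branch lengths in substitutions/site.

    ``model="yule"`` grows the tree by random leaf splitting with exponential
    branch lengths; ``model="coalescent-like"`` merges random lineage pairs
    with exponential waiting times (ultrametric).  Branch lengths are scaled so
    the mean root-to-tip depth equals ``mean_depth`` (default 0.10, i.e. the
    16S-divergence scale of a bacterial phylum).
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if model not in ("yule", "coalescent-like"):
        raise ValueError(f"unknown tree model {model!r}")
    rng = np.random.default_rng(seed)
    if labels is not None and len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    children: list[list[int]] = [[]]
    if model == "yule":
        leaves = []
        for _ in range(2):
            children.append([])
            children[0].append(len(children) - 1)
            leaves.append(len(children) - 1)
        while len(leaves) < n_tips:
            k = int(rng.integers(len(leaves)))
            node = leaves.pop(k)
            for _ in range(2):
                children.append([])
                children[node].append(len(children) - 1)
                leaves.append(len(children) - 1)
        lengths = rng.exponential(1.0, size=len(children))
    else:
        # Kingman-style pair merging; heights give ultrametric branch lengths
        heights = {}
        roots = []
        for _ in range(n_tips):
            children.append([])
            roots.append(len(children) - 1)
            heights[roots[-1]] = 0.0
        t = 0.0
        while len(roots) > 1:
            k = len(roots)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a, b = roots[i], roots[j]
            children.append([a, b])
            new = len(children) - 1
            heights[new] = t
            roots = [r for r in roots if r not in (a, b)] + [new]
        # re-root: node 0 was a placeholder; swap the final root into slot 0
        final = roots[0]
        children[0] = children[final]
        children[final] = []
        heights[0] = heights[final]
        lengths = np.zeros(len(children))
        stack = [0]
        while stack:
            nd = stack.pop()
            for c in children[nd]:
                lengths[c] = heights[nd] - heights.get(c, 0.0)
                stack.append(c)
    lengths[0] = 0.0

    leaf_ids = [i for i, c in enumerate(children) if not c and i != 0]
    node_labels = [""] * len(children)
    if labels is None:
        labels = [f"G{i + 1}" for i in range(n_tips)]
    for lab, i in zip(labels, leaf_ids):
        node_labels[i] = lab

    # scale mean root-to-tip depth to mean_depth
    depth_sum, n_below = _depth_stats(children, lengths)
    scale = mean_depth / (depth_sum[0] / n_below[0])
    lengths = lengths * scale
    newick = _newick(children, lengths, node_labels, 0) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _depth_stats(children: list[list[int]], lengths: np.ndarray):
    """Sum of node-to-tip distances and tip counts per node (postorder from root)."""
    depth_sum: dict[int, float] = {}
    n_below: dict[int, int] = {}
    stack: list[tuple[int, bool]] = [(0, False)]
    while stack:
        node, done = stack.pop()
        if not done:
            stack.append((node, True))
            stack.extend((c, False) for c in children[node])
        elif not children[node]:
            depth_sum[node] = 0.0
            n_below[node] = 1
        else:
            depth_sum[node] = sum(
                depth_sum[c] + lengths[c] * n_below[c] for c in children[node]
            )
            n_below[node] = sum(n_below[c] for c in children[node])
    return depth_sum, n_below


@dataclasses.dataclass
class PaintedTrait:
    """A painted binary trait with its ground truth."""

    trait: dict[str, bool]
    clades: list[tuple[str, ...]]
    true_depth: float


def paint_trait(
    tree: dendropy.Tree | TreeIndex,
    target_depth: float,
    p_in: float = 1.0,
    p_out: float = 0.0,
    seed: int | np.random.SeedSequence | None = 0,
    min_cover: float = 0.20,
) -> PaintedTrait:
    """Paint a binary trait on clades whose mean tip depth is near ``target_depth``.

    Non-nested internal clades closest in mean depth to the target are selected
    until at least ``min_cover`` of the tips are covered; tips inside selected
    clades are positive with probability ``p_in``, outside with ``p_out``.  The
    realized mean depth of the selected clades is returned as ground truth.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    rng = np.random.default_rng(seed)
    internal = [i for i in range(idx.n_nodes) if not idx.is_leaf[i]]
    order = sorted(internal, key=lambda i: abs(idx.mean_depth[i] - target_depth))
    covered = np.zeros(idx.n_tips, dtype=bool)
    selected: list[int] = []
    need = min_cover * idx.n_tips
    for i in order:
        tips = idx.tips_below[i]
        if covered[tips].any():
            continue
        selected.append(i)
        covered[tips] = True
        if covered.sum() >= need:
            break
    inside = covered
    draw = rng.random(idx.n_tips)
    positive = np.where(inside, draw < p_in, draw < p_out)
    return PaintedTrait(
        trait={l: bool(positive[t]) for t, l in enumerate(idx.tip_labels)},
        clades=[tuple(idx.tip_labels[t] for t in idx.tips_below[i]) for i in selected],
        true_depth=float(np.mean([idx.mean_depth[i] for i in selected])),
    )


# ---------------------------------------------------------------------------
# counts, metadata, raw annotations
# ---------------------------------------------------------------------------

def _family_pool(n_families: int, amap: ActivityMap, rng: np.random.Generator) -> list[str]:
    mapped = sorted({label for label, _ in amap.items()})
    fillers = [f"GT{i}" for i in range(1, 121)] + [f"CBM{i}" for i in range(1, 61)]
    pool = mapped + [f for f in fillers if f not in mapped]
    if n_families > len(pool):
        raise ValueError(f"at most {len(pool)} families supported")
    chosen = list(mapped[:n_families])
    if len(chosen) < n_families:
        extra = rng.choice(
            [f for f in pool if f not in chosen],
            size=n_families - len(chosen), replace=False,
        )
        chosen += [str(f) for f in extra]
    return sorted(chosen)


def simulate_counts(
    config: SimulationConfig, amap: ActivityMap | None = None
) -> tuple[pd.DataFrame, list[GenomeMetadata]]:
    """Simulate the genome x family count matrix and matching metadata.

    Each phylum draws a family profile from a Dirichlet around a shared base
    profile (concentration controls phylum distinctness); each habitat tilts a
    subset of families multiplicatively; per-genome totals are Poisson and the
    family split multinomial.
    """
    amap = amap or default_activity_map()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    families = _family_pool(config.n_families, amap, rng)
    nf = len(families)
    base_w = rng.lognormal(mean=0.0, sigma=1.5, size=nf)
    base = base_w / base_w.sum()
    habitats = list(_HABITAT_POOL[: config.n_habitats])
    tilt = {}
    for hab in habitats:
        mult = np.ones(nf)
        n_aff = max(1, int(round(config.habitat_affected_fraction * nf)))
        affected = rng.choice(nf, size=n_aff, replace=False)
        mult[affected] = np.exp(config.habitat_effect_size * rng.normal(size=n_aff))
        tilt[hab] = mult

    counts = []
    genome_ids = []
    metadata = []
    p16 = [config.p_16s_single, config.p_16s_missing,
           1.0 - config.p_16s_single - config.p_16s_missing]
    for pi in range(config.n_phyla):
        phylum = f"phylum_{pi + 1:02d}"
        alpha = config.phylum_profile_concentration * nf * base
        profile = rng.dirichlet(alpha)
        home = habitats[pi % len(habitats)]
        for gi in range(config.genomes_per_phylum):
            if config.confound_habitat:
                hab = home if rng.random() < 0.8 else habitats[int(rng.integers(len(habitats)))]
            else:
                hab = habitats[int(rng.integers(len(habitats)))]
            p = profile * tilt[hab]
            p = p / p.sum()
            total = rng.poisson(config.mean_cazymes_per_genome)
            row = rng.multinomial(total, p) if total > 0 else np.zeros(nf, dtype=int)
            gid = f"{phylum}_MAG{gi + 1:04d}"
            genome_ids.append(gid)
            counts.append(row)
            n16 = int(rng.choice([1, 0, 2], p=p16))
            metadata.append(GenomeMetadata(gid, phylum, hab, "high", n16))
    cm = pd.DataFrame(np.array(counts), index=pd.Index(genome_ids, name="genome_id"),
                      columns=families)
    cm = cm.loc[:, cm.sum(axis=0) > 0]
    return cm, metadata


def write_raw_annotations(
    counts: pd.DataFrame,
    annotations_path: str | Path,
    signalp_path: str | Path,
    config: SimulationConfig | None = None,
    amap: ActivityMap | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> int:
    """Expand a count matrix into per-gene annotation rows plus signal-peptide flags.

    E-values are sampled log-uniformly below the 1e-20 confidence threshold for
    the configured pass fraction of genes and above it for the rest; genes of
    mapped activities carry a signal peptide with the configured probability.
    Returns the number of gene rows written.
    """
    config = config or SimulationConfig()
    amap = amap or default_activity_map()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.evalue_range
    log_lo, log_thr, log_hi = np.log10(lo), -20.0, np.log10(hi)
    n_written = 0
    with open(annotations_path, "w", encoding="utf-8") as fa, \
            open(signalp_path, "w", encoding="utf-8") as fs:
        fa.write("genome_id\tgene_id\tfamily\te_value\n")
        fs.write("gene_id\tsignal_peptide\n")
        for gid, row in counts.iterrows():
            g = 0
            for fam, c in row.items():
                act = amap.lookup(fam)
                for _ in range(int(c)):
                    g += 1
                    gene = f"{gid}_g{g:05d}"
                    if rng.random() < config.evalue_pass_fraction:
                        ev = 10 ** rng.uniform(log_lo, log_thr)
                    else:
                        ev = 10 ** rng.uniform(log_thr + 0.05, log_hi)
                    sp = act != UNASSIGNED and rng.random() < config.signal_peptide_fraction
                    fa.write(f"{gid}\t{gene}\t{fam}\t{ev:.6g}\n")
                    fs.write(f"{gene}\t{int(sp)}\n")
                    n_written += 1
    return n_written


def generate_trees(
    metadata: Sequence[GenomeMetadata],
    config: SimulationConfig,
    usable_genomes: Sequence[str] | None = None,
) -> dict[str, dendropy.Tree]:
    """One simulated phylogeny per phylum, tips labelled by genome id.

    Only genomes in ``usable_genomes`` (e.g. the single-copy-16S set) get tips;
    phyla with fewer than two usable genomes are skipped.
    """
    usable = set(usable_genomes) if usable_genomes is not None else {
        m.genome_id for m in metadata
    }
    by_phylum: dict[str, list[str]] = {}
    for m in metadata:
        if m.genome_id in usable:
            by_phylum.setdefault(m.phylum, []).append(m.genome_id)
    seeds = np.random.SeedSequence(config.seed).spawn(len(by_phylum) + 100)
    trees = {}
    for i, phylum in enumerate(sorted(by_phylum)):
        ids = by_phylum[phylum]
        if len(ids) < 2:
            continue
        trees[phylum] = simulate_tree(
            len(ids), model=config.tree_model, seed=seeds[i],
            mean_depth=config.tree_mean_depth, labels=ids,
        )
    return trees


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Simulate a full input set and write it to ``outdir``.

    Emits ``annotations.tsv``, ``signalp.tsv``, ``metadata.tsv``,
    ``trees/<phylum>.nwk`` and ``truth.json`` (configuration and ground-truth
    bookkeeping).  Returns the paths written.
    """
    from .conservation import filter_for_phylogeny

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)
    amap = default_activity_map()
    counts, metadata = simulate_counts(config, amap)
    ann = outdir / "annotations.tsv"
    sp = outdir / "signalp.tsv"
    n_genes = write_raw_annotations(counts, ann, sp, config, amap,
                                    seed=np.random.SeedSequence(config.seed).spawn(2)[1])
    meta_path = outdir / "metadata.tsv"
    write_metadata(metadata, meta_path)
    usable = filter_for_phylogeny(metadata)
    trees = generate_trees(metadata, config, usable_genomes=usable)
    paths = {"annotations": str(ann), "signalp": str(sp), "metadata": str(meta_path)}
    for phylum, tree in trees.items():
        p = outdir / "trees" / f"{phylum}.nwk"
        write_tree(tree, p)
        paths[f"tree:{phylum}"] = str(p)
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_genomes": len(metadata),
        "n_genes_written": n_genes,
        "n_usable_16s": len(usable),
        "families": list(counts.columns),
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    paths["truth"] = str(truth_path)
    return paths
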