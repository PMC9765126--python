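"""Descriptive CAZyme profiling: filtering, counting, grouping and enrichment.

The unit of counting throughout is the (genome, gene, family) pair produced by
:mod:`cazytrait.io_formats` deduplication: a gene hit by several domains of the
same family counts once, hits to different families count once each.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ACTIVITY_CLASSES,
    UNASSIGNED,
    ActivityMap,
    AnnotationRecord,
    FamilyLabel,
    GenomeMetadata,
    ValidationError,
    metadata_frame,
)

__all__ = [
    "filter_by_evalue",
    "classify_activity",
    "build_matrices",
    "per_genome_summary",
    "per_group_summary",
    "activity_prevalence",
    "extracellular_share",
    "habitat_enrichment",
    "top_family_profile",
    "EnrichmentTable",
]

#: Default annotation confidence threshold (inclusive).
DEFAULT_EVALUE_THRESHOLD = 1e-20


def filter_by_evalue(
    records: Sequence[AnnotationRecord], threshold: float = DEFAULT_EVALUE_THRESHOLD
) -> list[AnnotationRecord]:
    """Keep records whose E-value is at or below ``threshold`` (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [r for r in records if r.e_value <= threshold]


def classify_activity(label: str | FamilyLabel, amap: ActivityMap) -> str:
    """Map a family label to one of the 14 activity classes or ``unassigned``."""
    return amap.lookup(label)


def build_matrices(
    records: Sequence[AnnotationRecord],
    amap: ActivityMap,
    metadata: Sequence[GenomeMetadata],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the genome x family count matrix and genome x activity trait matrix.

    Every genome in ``metadata`` gets a row; genomes without annotations are
    all-zero (a genome can lack CAZymes).  A record whose genome is absent from
    the metadata is an error.  The trait matrix is boolean: a genome is
    positive for an activity iff it has at least one gene of a mapped family.
    """
    genomes = [m.genome_id for m in metadata]
    known = set(genomes)
    missing = sorted({r.genome_id for r in records} - known)
    if missing:
        raise ValidationError(
            f"records reference genomes absent from metadata: {', '.join(missing)}"
        )
    if records:
        df = pd.DataFrame(
            {
                "genome_id": [r.genome_id for r in records],
                "family": [r.family_label for r in records],
            }
        )
        counts = (
            df.groupby(["genome_id", "family"], sort=False).size().unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame(index=pd.Index([], name="genome_id"))
    counts = counts.reindex(index=genomes, fill_value=0).astype(int)
    counts.index.name = "genome_id"
    counts = counts.loc[:, counts.sum(axis=0) > 0]  # no all-zero family columns
    counts = counts.sort_index(axis=1)

    traits = pd.DataFrame(
        False, index=pd.Index(genomes, name="genome_id"), columns=list(ACTIVITY_CLASSES)
    )
    for fam in counts.columns:
        act = amap.lookup(fam)
        if act != UNASSIGNED:
            traits.loc[counts[fam] > 0, act] = True
    return counts, traits


def per_genome_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Total CAZyme gene count and distinct-family richness per genome."""
    return pd.DataFrame(
        {
            "total_cazymes": counts.sum(axis=1).astype(int),
            "n_families": (counts > 0).sum(axis=1).astype(int),
        },
        index=counts.index,
    )


def per_group_summary(
    summaries: pd.DataFrame,
    metadata: Sequence[GenomeMetadata],
    group_by: str = "phylum",
    min_group_size: int = 10,
) -> pd.DataFrame:
    """Mean/SEM/median/quartile summaries of abundance and richness per group.

    Groups with fewer than ``min_group_size`` genomes are pooled into
    ``"Other"``.  SEM is undefined (missing) for single-genome groups.
    """
    if group_by not in ("phylum", "habitat"):
        raise ValueError("group_by must be 'phylum' or 'habitat'")
    meta = metadata_frame(metadata)
    df = summaries.join(meta[group_by], how="left")
    sizes = df[group_by].value_counts()
    small = set(sizes[sizes < min_group_size].index)
    df["group"] = df[group_by].where(~df[group_by].isin(small), "Other")
    rows = []
    for group, sub in df.groupby("group"):
        for metric in ("total_cazymes", "n_families"):
            v = sub[metric].to_numpy(dtype=float)
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "n_genomes": len(v),
                    "mean": v.mean(),
                    "sem": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                    "median": float(np.median(v)),
                    "q1": float(np.percentile(v, 25)),
                    "q3": float(np.percentile(v, 75)),
                }
            )
    out = pd.DataFrame(rows)
    order = (
        out[out.metric == "total_cazymes"]
        .sort_values("n_genomes", ascending=False)["group"]
        .tolist()
    )
    out["group"] = pd.Categorical(out["group"], categories=order, ordered=True)
    return out.sort_values(["group", "metric"]).reset_index(drop=True)


def activity_prevalence(
    traits: pd.DataFrame,
    metadata: Sequence[GenomeMetadata],
    group_by: str = "phylum",
) -> pd.DataFrame:
    """Share of genomes per group positive for each activity, in percent."""
    if group_by not in ("phylum", "habitat"):
        raise ValueError("group_by must be 'phylum' or 'habitat'")
    meta = metadata_frame(metadata)
    df = traits.join(meta[group_by], how="left")
    rows = []
    for group, sub in df.groupby(group_by, sort=False):
        for act in traits.columns:
            rows.append(
                {
                    "group": group,
                    "activity": act,
                    "n_genomes": len(sub),
                    "pct_genomes": 100.0 * sub[act].mean(),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["n_genomes", "group", "activity"], ascending=[False, True, True]
    ).reset_index(drop=True)


def extracellular_share(
    records: Sequence[AnnotationRecord], amap: ActivityMap
) -> pd.DataFrame:
    """Per activity: gene counts and the percentage carrying a signal peptide.

    Activities with no genes are reported with a missing percentage (absence,
    not zero).
    """
    totals = {a: 0 for a in ACTIVITY_CLASSES}
    extra = {a: 0 for a in ACTIVITY_CLASSES}
    for r in records:
        act = amap.lookup(r.family_label)
        if act == UNASSIGNED:
            continue
        totals[act] += 1
        if r.signal_peptide:
            extra[act] += 1
    return pd.DataFrame(
        {
            "activity": list(ACTIVITY_CLASSES),
            "n_total": [totals[a] for a in ACTIVITY_CLASSES],
            "n_extracellular": [extra[a] for a in ACTIVITY_CLASSES],
            "pct_extracellular": [
                100.0 * extra[a] / totals[a] if totals[a] else np.nan
                for a in ACTIVITY_CLASSES
            ],
        }
    )


@dataclasses.dataclass
class EnrichmentTable:
    """Habitat x activity relative-abundance shares and their enrichment.

    ``share`` rows sum to one over assigned activities; ``grand_mean`` is the
    unweighted mean of habitat shares (or record-weighted when requested);
    ``delta = share - grand_mean``.  A ratio scale is available as ``ratio``.
    """

    share: pd.DataFrame
    grand_mean: pd.Series
    delta: pd.DataFrame

    @property
    def ratio(self) -> pd.DataFrame:
        return self.share.divide(self.grand_mean, axis=1)


def habitat_enrichment(
    records: Sequence[AnnotationRecord],
    amap: ActivityMap,
    metadata: Sequence[GenomeMetadata],
    weighted: bool = False,
) -> EnrichmentTable:
    """Relative abundance of each activity per habitat, against the grand mean.

    Only genes whose family maps to an assigned activity participate.  Habitats
    with zero assignable genes are excluded with a warning.
    """
    habitat_of = {m.genome_id: m.habitat for m in metadata}
    rows = []
    for r in records:
        act = amap.lookup(r.family_label)
        if act == UNASSIGNED:
            continue
        hab = habitat_of.get(r.genome_id)
        if hab is None:
            raise ValidationError(f"record genome {r.genome_id!r} absent from metadata")
        rows.append((hab, act))
    counts = (
        pd.DataFrame(rows, columns=["habitat", "activity"])
        .groupby(["habitat", "activity"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(ACTIVITY_CLASSES), fill_value=0)
        if rows
        else pd.DataFrame(columns=list(ACTIVITY_CLASSES))
    )
    empty = sorted(set(habitat_of.values()) - set(counts.index))
    if empty:
        warnings.warn(
            f"habitats with zero assignable CAZymes excluded: {', '.join(empty)}"
        )
    share = counts.div(counts.sum(axis=1), axis=0)
    if weighted:
        total = counts.sum(axis=0)
        grand_mean = total / total.sum()
    else:
        grand_mean = share.mean(axis=0)
    return EnrichmentTable(share=share, grand_mean=grand_mean, delta=share - grand_mean)


def top_family_profile(
    counts: pd.DataFrame,
    metadata: Sequence[GenomeMetadata],
    k: int = 30,
) -> pd.DataFrame:
    """Per-habitat relative abundance of the ``k`` globally most abundant families."""
    meta = metadata_frame(metadata)
    top = counts.sum(axis=0).sort_values(ascending=False, kind="stable").head(k).index
    df = counts.join(meta["habitat"], how="left")
    rows = []
    for hab, sub in df.groupby("habitat", sort=True):
        sub_counts = sub.drop(columns="habitat")
        total = sub_counts.to_numpy().sum()
        for fam in top:
            rows.append(
                {
                    "habitat": hab,
                    "family": fam,
                    "relative_abundance": sub_counts[fam].sum() / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)
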