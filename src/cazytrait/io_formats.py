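"""Readers and writers for the tables and trees the pipeline consumes.

All tabular inputs are tab-separated UTF-8 with a header line; lines starting
with ``#`` are ignored.  Trees are Newick with branch lengths in
substitutions/site.  Every reader validates its input strictly and reports
malformed rows instead of silently dropping them.
"""
from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "CAZY_CLASSES",
    "ACTIVITY_CLASSES",
    "UNASSIGNED",
    "FormatError",
    "ValidationError",
    "FamilyLabel",
    "AnnotationRecord",
    "GenomeMetadata",
    "ReadReport",
    "ActivityMap",
    "read_annotations",
    "write_annotations",
    "read_signal_peptides",
    "merge_signal_peptides",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
    "read_tree",
    "write_tree",
    "read_activity_map",
    "default_activity_map",
]

#: The six CAZy enzyme classes.
CAZY_CLASSES = ("GH", "GT", "CE", "CBM", "PL", "AA")

#: The 14 target-activity classes used to group CAZy families by the main
#: carbohydrate they attack.  Order is fixed and used for all output tables.
ACTIVITY_CLASSES = (
    "cellulases",
    "xylanases/xyloglucanases",
    "beta-glucosidases/beta-xylosidases",
    "chitinases/chitosanases",
    "alpha-glucanases",
    "beta-glucanases",
    "mannanases",
    "arabinogalactanases",
    "other hemicellulases",
    "pectinases",
    "carragenases/agarases",
    "peptidoglycanases",
    "glycoconjugate-degrading enzymes",
    "lytic polysaccharide monooxygenases",
)

UNASSIGNED = "unassigned"


class FormatError(ValueError):
    """A file does not conform to the expected format (e.g. missing column)."""


class ValidationError(ValueError):
    """Content-level validation failed (e.g. duplicate genome ids)."""


_FAMILY_RE = re.compile(r"^(GH|GT|CE|CBM|PL|AA)(\d+)(?:_(.+))?$")


@dataclasses.dataclass(frozen=True)
class FamilyLabel:
    """A parsed CAZy family label such as ``GH5``, ``GH5_7`` or ``GT2_Glycos_transf_2``.

    ``subfamily`` is set only for numeric subfamily suffixes; a non-numeric
    suffix (dbCAN HMM naming) is preserved in ``suffix`` and the label maps to
    its base family for activity lookup.
    """

    cazy_class: str
    family: int
    subfamily: int | None = None
    suffix: str | None = None

    @classmethod
    def parse(cls, text: str) -> "FamilyLabel":
        text = text.strip()
        if text.endswith(".hmm"):
            text = text[: -len(".hmm")]
        m = _FAMILY_RE.match(text)
        if m is None:
            raise ValidationError(f"not a valid CAZy family label: {text!r}")
        cazy_class, family, tail = m.group(1), int(m.group(2)), m.group(3)
        if family <= 0:
            raise ValidationError(f"family number must be positive: {text!r}")
        if tail is None:
            return cls(cazy_class, family)
        if tail.isdigit():
            sub = int(tail)
            if sub <= 0:
                raise ValidationError(f"subfamily number must be positive: {text!r}")
            return cls(cazy_class, family, subfamily=sub)
        return cls(cazy_class, family, suffix=tail)

    @property
    def base(self) -> str:
        """Family-level label without any subfamily/suffix, e.g. ``GH5``."""
        return f"{self.cazy_class}{self.family}"

    def __str__(self) -> str:
        if self.subfamily is not None:
            return f"{self.base}_{self.subfamily}"
        if self.suffix is not None:
            return f"{self.base}_{self.suffix}"
        return self.base


@dataclasses.dataclass(frozen=True)
class AnnotationRecord:
    """One gene-level CAZyme assignment."""

    genome_id: str
    gene_id: str
    family_label: str
    e_value: float
    signal_peptide: bool = False

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(
                f"E-value must be non-negative: {self.e_value!r} "
                f"({self.genome_id}/{self.gene_id})"
            )
        # raises if the label is invalid
        FamilyLabel.parse(self.family_label)

    @property
    def family(self) -> FamilyLabel:
        return FamilyLabel.parse(self.family_label)


@dataclasses.dataclass(frozen=True)
class GenomeMetadata:
    """Per-genome metadata: taxonomy, habitat, quality class and 16S status."""

    genome_id: str
    phylum: str
    habitat: str
    quality: str = "high"
    n_16S_copies: int = 1

    def __post_init__(self) -> None:
        if not self.phylum or not self.habitat:
            raise ValidationError(
                f"phylum and habitat must be non-empty for {self.genome_id!r}"
            )
        if self.quality not in ("high", "other"):
            raise ValidationError(
                f"quality must be 'high' or 'other', got {self.quality!r}"
            )
        if self.n_16S_copies < 0:
            raise ValidationError("n_16S_copies must be non-negative")


@dataclasses.dataclass
class ReadReport:
    """Accounting of a reader run: rows seen, rejected and collapsed."""

    path: str = ""
    n_rows: int = 0
    n_records: int = 0
    n_malformed: int = 0
    n_duplicates_collapsed: int = 0
    errors: list[str] = dataclasses.field(default_factory=list)
    decisions: list[str] = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

_GENERIC_COLS = {
    "genome": ("genome_id", "genome", "mag", "mag_id"),
    "gene": ("gene_id", "gene", "protein_id", "protein"),
    "family": ("family", "family_label", "cazy_family", "hmm_profile"),
    "e_value": ("e_value", "evalue", "e-value", "e value"),
}

_DBCAN_COLS = {
    "genome": ("genome id", "genome_id", "genome"),
    "gene": ("gene id", "gene_id", "query"),
    "family": ("hmm profile", "hmm_profile", "family hmm"),
    "e_value": ("e value", "e_value", "evalue"),
}


def _resolve_columns(header: list[str], wanted: Mapping[str, tuple[str, ...]],
                     optional: tuple[str, ...] = ()) -> dict[str, int]:
    lower = [h.strip().lower() for h in header]
    out: dict[str, int] = {}
    for key, aliases in wanted.items():
        for alias in aliases:
            if alias in lower:
                out[key] = lower.index(alias)
                break
        else:
            if key not in optional:
                raise FormatError(
                    f"missing required column {key!r} "
                    f"(accepted names: {', '.join(aliases)})"
                )
    return out


def _iter_rows(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_annotations(
    path: str | Path,
    dialect: str = "generic_tsv",
    genome_id: str | None = None,
) -> tuple[list[AnnotationRecord], ReadReport]:
    """Read a per-gene CAZyme annotation table.

    Parameters
    ----------
    path
        Tab-separated file with a header.
    dialect
        ``"generic_tsv"`` expects genome/gene/family/E-value columns (an
        optional ``signal_peptide`` column is honoured); ``"dbcan_hmmer"``
        accepts the hmmscan-style domain table written by dbCAN (one row per
        domain hit, HMM profile names ending in ``.hmm``).
    genome_id
        For ``dbcan_hmmer`` tables that lack a genome column (dbCAN runs per
        genome), the genome id to assign to every row.

    Returns
    -------
    records, report
        Validated, deduplicated records (a gene hit by several domains of the
        same family counts once; the smallest E-value is kept and
        signal-peptide flags are OR-ed) and a :class:`ReadReport` with counts
        of malformed and collapsed rows.
    """
    if dialect not in ("generic_tsv", "dbcan_hmmer"):
        raise ValueError(f"unknown dialect {dialect!r}")
    report = ReadReport(path=str(path))
    rows = _iter_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    colspec = _GENERIC_COLS if dialect == "generic_tsv" else _DBCAN_COLS
    optional = ("genome",) if dialect == "dbcan_hmmer" and genome_id else ()
    cols = _resolve_columns(header, colspec, optional=optional)
    lower = [h.strip().lower() for h in header]
    sp_col = lower.index("signal_peptide") if "signal_peptide" in lower else None

    best: dict[tuple[str, str, str], AnnotationRecord] = {}
    order: list[tuple[str, str, str]] = []
    for lineno, fields in rows:
        report.n_rows += 1
        try:
            if len(fields) <= max(cols.values()):
                raise ValidationError("too few columns")
            g = fields[cols["genome"]].strip() if "genome" in cols else genome_id
            if not g:
                raise ValidationError("empty genome id")
            gene = fields[cols["gene"]].strip()
            fam = str(FamilyLabel.parse(fields[cols["family"]]))
            ev = float(fields[cols["e_value"]])
            sp = False
            if sp_col is not None and len(fields) > sp_col:
                sp = fields[sp_col].strip().lower() in ("1", "true", "yes", "y")
            rec = AnnotationRecord(g, gene, fam, ev, sp)
        except (ValidationError, ValueError) as exc:
            report.n_malformed += 1
            report.errors.append(f"line {lineno}: {exc}")
            continue
        key = (rec.genome_id, rec.gene_id, rec.family_label)
        if key in best:
            report.n_duplicates_collapsed += 1
            old = best[key]
            best[key] = AnnotationRecord(
                rec.genome_id, rec.gene_id, rec.family_label,
                min(old.e_value, rec.e_value),
                old.signal_peptide or rec.signal_peptide,
            )
        else:
            best[key] = rec
            order.append(key)
    records = [best[k] for k in order]
    report.n_records = len(records)
    if report.n_duplicates_collapsed:
        report.decisions.append(
            "duplicate (genome, gene, family) rows collapsed; min E-value kept"
        )
    return records, report


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tgene_id\tfamily\te_value\tsignal_peptide\n")
        for r in records:
            fh.write(
                f"{r.genome_id}\t{r.gene_id}\t{r.family_label}\t"
                f"{r.e_value:.6g}\t{int(r.signal_peptide)}\n"
            )


def read_signal_peptides(path: str | Path) -> dict[str, bool]:
    """Read a two-column ``gene_id -> flag`` table (SignalP-style summary)."""
    flags: dict[str, bool] = {}
    rows = _iter_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    if len(header) < 2:
        raise FormatError(f"{path}: expected two columns (gene_id, signal_peptide)")
    for lineno, fields in rows:
        if len(fields) < 2:
            raise FormatError(f"{path} line {lineno}: too few columns")
        flags[fields[0].strip()] = fields[1].strip().lower() in ("1", "true", "yes", "y")
    return flags


def merge_signal_peptides(
    records: Iterable[AnnotationRecord], flags: Mapping[str, bool]
) -> list[AnnotationRecord]:
    """Return records with signal-peptide flags merged in by gene id."""
    return [
        dataclasses.replace(r, signal_peptide=flags.get(r.gene_id, r.signal_peptide))
        for r in records
    ]


# ---------------------------------------------------------------------------
# genome metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    """Read per-genome metadata (phylum, habitat, quality, 16S copy number)."""
    rows = _iter_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    cols = _resolve_columns(
        header,
        {
            "genome": ("genome_id", "genome", "mag", "mag_id"),
            "phylum": ("phylum",),
            "habitat": ("habitat", "ecosystem"),
        },
    )
    lower = [h.strip().lower() for h in header]
    qcol = lower.index("quality") if "quality" in lower else None
    ncol = None
    for alias in ("n_16s_copies", "n_16s", "n16s"):
        if alias in lower:
            ncol = lower.index(alias)
            break
    out: list[GenomeMetadata] = []
    seen: dict[str, int] = {}
    for lineno, fields in rows:
        gid = fields[cols["genome"]].strip()
        seen[gid] = seen.get(gid, 0) + 1
        out.append(
            GenomeMetadata(
                genome_id=gid,
                phylum=fields[cols["phylum"]].strip(),
                habitat=fields[cols["habitat"]].strip(),
                quality=fields[qcol].strip() if qcol is not None else "high",
                n_16S_copies=int(fields[ncol]) if ncol is not None else 1,
            )
        )
    dups = sorted(g for g, n in seen.items() if n > 1)
    if dups:
        raise ValidationError(f"duplicate genome ids in {path}: {', '.join(dups)}")
    return out


def write_metadata(metadata: Iterable[GenomeMetadata], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tphylum\thabitat\tquality\tn_16S_copies\n")
        for m in metadata:
            fh.write(
                f"{m.genome_id}\t{m.phylum}\t{m.habitat}\t{m.quality}\t{m.n_16S_copies}\n"
            )


def metadata_frame(metadata: Iterable[GenomeMetadata]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by genome id."""
    df = pd.DataFrame([dataclasses.asdict(m) for m in metadata])
    return df.set_index("genome_id")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree over genome ids.

    Unrooted input (a basal trifurcation) is accepted and treated as rooted at
    the outermost node, recorded in ``tree.annotations``.  Zero-length branches
    are permitted; a missing branch length is an error naming the node.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip labels in {path}: {exc}") from exc
    tree.suppress_unifurcations()
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dup = sorted({l for l in labels if labels.count(l) > 1})
    if dup:
        raise ValidationError(f"duplicate tip labels in {path}: {', '.join(dup)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else f"internal node over {sorted(l.taxon.label for l in node.leaf_iter())[:3]}"
            raise ValidationError(f"missing branch length at {name} in {path}")
        if node.edge.length < 0:
            raise ValidationError(f"negative branch length in {path}")
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        tree.annotations.add_new(
            "rooting", "input basal polytomy treated as root (rooted deterministically)"
        )
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


# ---------------------------------------------------------------------------
# activity map
# ---------------------------------------------------------------------------

class ActivityMap:
    """Lookup from CAZy family/subfamily to one of the 14 target-activity classes.

    Subfamily-level entries take precedence over family-level entries; labels
    with non-numeric suffixes fall back to their base family; families absent
    from the map return ``"unassigned"``.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._entries: dict[str, str] = {}
        for label, activity in entries.items():
            canonical = str(FamilyLabel.parse(label))
            if activity not in ACTIVITY_CLASSES and activity != UNASSIGNED:
                raise ValidationError(
                    f"unknown activity class {activity!r} for {label!r}"
                )
            self._entries[canonical] = activity

    def lookup(self, label: str | FamilyLabel) -> str:
        fam = label if isinstance(label, FamilyLabel) else FamilyLabel.parse(label)
        if fam.subfamily is not None:
            hit = self._entries.get(str(fam))
            if hit is not None:
                return hit
        return self._entries.get(fam.base, UNASSIGNED)

    def classes(self) -> tuple[str, ...]:
        """Distinct activity classes defined by the map (excluding unassigned)."""
        return tuple(
            sorted({a for a in self._entries.values() if a != UNASSIGNED},
                   key=ACTIVITY_CLASSES.index)
        )

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)


def read_activity_map(path: str | Path) -> ActivityMap:
    """Read a two-column ``family -> activity`` table."""
    rows = _iter_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    entries: dict[str, str] = {}
    for lineno, fields in rows:
        if len(fields) < 2:
            raise FormatError(f"{path} line {lineno}: expected two columns")
        entries[fields[0].strip()] = fields[1].strip()
    return ActivityMap(entries)


def default_activity_map() -> ActivityMap:
    """The bundled curated family -> activity map defining the 14 classes."""
    from importlib import resources

    with resources.files("cazytrait.data").joinpath("activity_map_default.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        entries: dict[str, str] = {}
        next(fh)  # header
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fam, act = line.split("\t")[:2]
            entries[fam] = act
    return ActivityMap(entries)
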