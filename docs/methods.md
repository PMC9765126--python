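# Methods

This note documents the models, estimators and design choices behind
`cazytrait`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, with which defaults, and
what the synthetic benchmarks do and do not demonstrate.

## Annotation model

The unit of analysis is the **gene-family pair**. dbCAN-style annotation is a
domain-level assignment: one gene may carry several domain hits to the same
CAZy family. `read_annotations` collapses duplicate (genome, gene, family)
rows to one record, keeping the smallest E-value and OR-ing signal-peptide
flags. Hits by the same gene to *different* families each count once. This
prevents multi-domain architectures from inflating per-genome counts while
preserving genuine multifunctionality.

Annotation confidence is filtered at `E ≤ 1e-20`, *inclusive* of the
boundary. Family labels follow CAZy nomenclature (`GH5`, `GH5_7`); labels with
non-numeric suffixes such as `GT2_Glycos_transf_2` (dbCAN HMM naming) are kept
verbatim for family-level statistics but resolve to their base family for
activity lookup.

### Activity map

The 14 target-activity classes are: cellulases; xylanases/xyloglucanases;
β-glucosidases/β-xylosidases; chitinases/chitosanases; α-glucanases;
β-glucanases; mannanases; arabinogalactanases; other hemicellulases;
pectinases; carragenases/agarases; peptidoglycanases;
glycoconjugate-degrading enzymes; lytic polysaccharide monooxygenases.
The bundled `activity_map_default.tsv` is this package's own curation of
characterized family activities (about 110 entries); subfamily entries
override family entries, and unmapped families — all GTs and CBMs among them —
return `unassigned` and are excluded from activity-level statistics ("targets
reliably assignable"). Users with their own curation can pass any two-column
table; `read_activity_map` validates class names.

## Profiling conventions

- Genomes present in the metadata but lacking annotations appear as all-zero
  rows: a genome can genuinely encode no CAZymes. Such genomes stay in
  summaries but are excluded from ordination (a zero vector has no direction).
- Group summaries report mean, **standard error of the mean**, median and
  quartiles; groups under 10 genomes pool into `Other`. SEM (not SD) is the
  "±" convention throughout.
- Habitat enrichment: per habitat, the share of assignable genes per activity
  (rows sum to 1); the grand mean is the **unweighted** mean of habitat shares,
  so enrichment deltas sum to zero across habitats by construction. A
  gene-count-weighted grand mean is available (`weighted=True`), and a ratio
  scale via `EnrichmentTable.ratio`; the default scale is the difference.

## Ordination

Families are filtered once, globally, to those holding strictly more than
0.1% of all annotated genes; filtering precedes normalization (the order is a
function-composition choice the caller can invert). Rows are scaled to unit
sum of squares, making Euclidean distance the chord distance (≤ √2 for
non-negative profiles). PCoA is classical metric scaling: double-center the
squared distances, eigendecompose, keep positive axes, report the full
spectrum including negative eigenvalues. PERMANOVA uses the standard pseudo-F
on among/within sums of squared distances with a label-shuffling null driven
by a numpy `Generator`; `p = (1 + #{F* ≥ F}) / (1 + n_perm)` so p can never be
zero. Defaults: 999 permutations; pairwise comparisons corrected by
Bonferroni (Holm and Benjamini-Hochberg available). PCoA and PERMANOVA are
implemented in-package to guarantee seeded, reproducible permutation streams
and negative-eigenvalue reporting; scikit-bio's implementations serve as
independent cross-checks in the test suite.

## Phylogenetic conservation

Both statistics operate per phylum on rooted trees with branch lengths in
substitutions/site (16S trees in the intended application), restricted to
high-quality genomes carrying exactly one 16S copy. Trees are used as given —
no ultrametric enforcement, since ML trees are additive — and polytomies are
allowed everywhere. Phyla with fewer than 21 usable tips (i.e. not "more than
20") are skipped with a reason.

### Abouheif's C_mean

The proximity between tips i and j is `1 / ∏ dd(v)` over the internal nodes v
on the path connecting them **through the root** (shared ancestors counted
once), where `dd(v)` is v's number of direct descendants. Anchors: 2-tip tree
→ 1/2; a cherry under a binary root → 1/4; opposite cherries of a balanced
4-tip tree → 1/8; star with k tips → 1/k. With W the row-normalized proximity
and x the centered trait, `C_mean = x'Wx / x'x`; the 2-tip antisymmetric case
gives exactly −1. The default trait is binary presence/absence per activity;
per-genome gene counts can be supplied instead (`counts=` in the suite), as
the statistic accepts any quantitative variable. p-values come from tip-label
permutations with the +1 convention.

### consenTRAIT trait depth

`find_positive_clades` returns the maximal (non-nested) clades with ≥2 tips
whose positive-tip fraction is at least `min_fraction` (default 0.90 — the
established threshold of the consenTRAIT formulation; configurable), plus
positive singleton tips outside any such clade. Each clade contributes the
mean branch-length distance from its ancestral node to **all** its member
tips; a singleton contributes `singleton_factor` (default 0.5, configurable
in [0, 1]) times its terminal branch length. `τ_D` is the unweighted mean over
those contributions (a tip-count-weighted variant would emphasize large
clades; unweighted keeps each independent trait gain equally informative).

The randomization test shuffles trait labels among tips (preserving the
positive count) `n_perm` times (default 1000) and reports the **plain
fraction** of permuted `τ_D` values ≥ observed — so p can be exactly 0 or,
for invariant configurations (all tips positive), exactly 1. A
`plus_one=True` variant gives the (1+k)/(1+n) convention for downstream use.
The identity conversion is `identity = 1 − 2·τ_D`, `divergence% = 200·τ_D`;
values of τ_D above 0.5 would leave the identity scale and are returned as
computed.

Correctness is anchored two ways: exhaustive agreement with a brute-force
all-internal-node scan over every trait assignment on random 4–8 tip trees,
and closed forms on the unit balanced 4-tip tree (all-positive → τ_D = 2;
one cherry → 1; one singleton → 0.5).

## Synthetic data generator

The generator emulates a down-scaled genome catalog. Defaults (chosen once as
this package's model of a realistic catalog, then left alone):

| parameter | default | rationale |
|---|---|---|
| phyla × genomes | 10 × 50 | enough groups for ordination and ≥20-tip trees |
| families | 200 | order of the abundant-family pool of a real catalog |
| mean CAZymes/genome | 80 (Poisson) | between the ~28 and ~122 per-genome means of major phyla |
| profile concentration | 1.0 | phylum profiles distinct: taxonomy explains more variance than habitat |
| habitat effect | 0.5 (log-normal tilt on 15% of families) | habitat effect present and significant but weaker than phylogeny |
| 16S copy status | 0.78 single / 0.19 missing / 0.03 multiple | observed catalog proportions |
| E-values | log-uniform on [1e-40, 1e-5], 80% below 1e-20 | threshold bisects realistically |
| signal peptides | 20% of mapped genes | plausible extracellular share |
| tree depth | mean root-to-tip 0.10 | 16S divergence scale of a phylum |

Trees are simulated in-package (Yule leaf-splitting with exponential branch
lengths, or a coalescent-like ultrametric variant), rescaled to the target
mean depth, so that every random draw flows from one numpy seed sequence.
Traits are painted by selecting non-nested clades whose mean tip depth is
closest to a target, until ≥20% of tips are covered, then setting tips
positive with probability `p_in` inside and `p_out` outside; the realized
mean clade depth is returned as ground truth. Painting clades directly (rather
than thresholding a Brownian character) gives an explicit target against which
τ_D recovery is measured.

A confounded mode ties habitat to phylum (80% association) to reproduce the
situation where habitat differences are driven by phylogenetic composition.

**What passing tests show** — that the estimators are exact against brute
force, calibrated under their nulls, and able to recover planted conservation
depths and group structure at catalog-like scale. **What they do not show** —
anything about real annotation error structure (HMM score correlations,
incomplete genomes, chimeric bins), real tree uncertainty, or the biological
correctness of the bundled activity curation.

## Numerical choices and degenerate inputs

- Permutation p-values: seeded `numpy.random.Generator` streams throughout;
  child seeds spawned per (phylum, activity) cell so results are independent
  of iteration order and reproducible cell-by-cell.
- Ties in permutation tests use `≥` on identically computed floats, so
  invariant configurations give p = 1 exactly.
- PCoA drops axes with eigenvalues below `1e-12 × max |eigenvalue|`;
  proportions explained are relative to the positive spectrum.
- Constant traits: C_mean raises "no variance" (flagged, not computed, in the
  suite table); τ_D with zero positives is undefined and raises; all-positive
  traits give the root clade with p = 1.
- Zero-length branches are legal everywhere; missing branch lengths are a
  read error naming the node.
- Problem sizes in the test-suite benchmarks (500 null replicates at 200
  permutations, 128-tip recovery trees, 200 PERMANOVA null simulations at
  n = 30) were chosen as the smallest sizes at which the calibration bands are
  statistically meaningful.

## Known limitations

- The bundled activity map is a curated default, not a community-ratified
  reference; family-to-activity assignments at subfamily resolution are
  deliberately sparse.
- One-factor PERMANOVA only; no interaction or nested designs.
- τ_D assumes the trait arises by descent within clades; heavy horizontal
  transfer breaks the clade-depth interpretation.
- The identity conversion assumes branch lengths are 16S substitutions/site;
  on other markers the divergence scale changes meaning.
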