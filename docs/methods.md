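# Methods

## Model and assumptions

A *positional cluster* is a maximal run of ≥ 2 genes on one chromosome in
which every consecutive pair of gene **start** coordinates is within the
distance threshold D (base pairs). The definition implies:

- **Start-to-start distance.** Gene length and end coordinates are ignored,
  even for long genes: two genes whose bodies overlap but whose starts are
  more than D apart do not chain. This is a deliberate modeling choice — the
  start is where transcription initiates and is the coordinate most robustly
  annotated across databases — but it means very long genes can "shadow"
  proximity that an end-aware metric would detect.
- **Strand-agnostic.** Neighboring genes influence each other's transcription
  regardless of orientation, so strand never enters the distance. Strand is
  still carried through all formats; strand-restricted analyses are done by
  pre-filtering the input gene list.
- **Expression selects, position clusters.** Expression values are used only
  to choose which genes enter the clustering (thresholding up/down-regulated
  sets); membership itself is purely positional.
- **Single global threshold.** One D for the whole genome, typically derived
  from mean gene density. Gene density varies along real chromosomes; the
  supported workflow for density questions is re-running at several
  thresholds (the clustered-gene set is provably monotone in D, which the
  tests verify), not a per-region threshold.
- **Chaining = single linkage at cutoff.** On sorted 1-D starts, the
  sequential rule equals single-linkage clustering cut at D. The test suite
  checks exact partition equality against a brute-force union-find oracle
  over all gene pairs, on 1000 random instances.

Ties: two genes with identical start coordinates are at distance 0 ≤ D and
always share a cluster; the within-chromosome sort breaks ties by (start,
end, name) so all outputs are deterministic. Chromosomes are processed in
order of first appearance in the input; cluster IDs are assigned
progressively across the whole run (1..N), never per chromosome, so IDs are
unique in the CLU file.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `threshold_bp` (D) | bp | none (required) | choose from mean gene density; 20 000 bp suits a gene-dense insect genome |
| filter `threshold` / `indices` / `combine` / `direction` | expression units | any/keep_ge over all indices | inclusive comparisons (≥ / ≤); NaN never passes, so unrepaired genes are dropped — run the NaN fixer first to keep them |
| randomization `n`, `runs`, `seed` | — | — | n is usually the observed clustered-gene count; 20 runs matches a typical control batch; sampling is without replacement (a gene *set*) |
| `ViewStyle.scaling` | — | `sqrt` | glyph **area** proportional to magnitude; `linear` makes the diameter proportional |
| `ViewStyle.min/max_diameter` | px | 3 / 28 | zero, negative and missing expression all collapse to `min_diameter` |

## Merging and repair

The position/expression join keeps only genes present in both inputs;
duplicates (by exact, case-sensitive name) keep their **first** instance and
are reported rather than averaged — aggregating probes is an analysis
decision the package refuses to automate. Ragged expression rows are
NaN-padded to the longest observed vector. Omitting the expression table
entirely yields all-zero vectors for pure positional clustering.

## Updating clusters

`add_genes` re-sorts and re-clusters the union of existing members and the
new genes with the same rule, renumbering IDs; origin is tracked through the
dataset label, so merged clusters show which input each gene came from.
Because the CLU file no longer contains genes discarded as singletons in the
original run, those genes cannot be resurrected by an update; when that
matters, re-run the clustering on the merged GDFs instead (the CLI supports
both paths). A differing threshold in an update is allowed but warned about.

## Significance testing

Random runs form the sample; the observed value is the hypothesized mean μ of
a one-sample t-test (two-sided, df = runs − 1, p from the Student's t
distribution). Three statistics are exposed: cluster count (default),
clustered-gene count, and mean cluster size; a run with zero clusters
contributes mean size 0. When all random runs are identical (zero variance —
common with an all-isolated pool) the report is returned as degenerate with
the raw sample moments instead of a t and p. The per-run summary table is
also written as plain text so the sample can be exported to any external
statistics package.

## Visualization

Both views are emitted as self-contained SVG. The multiple-cluster view draws
each chromosome from its leftmost to its rightmost cluster, left-aligned,
with a single shared bp-to-pixel factor so relative lengths are comparable;
each cluster is one glyph at its **first gene's start**, labeled with its ID
and that position in kbp. The single-cluster view draws one track per
expression stage with glyph size following the stage's value. Negative
expression values (log-ratios) render at point size like zero, with a
warning; missing values render hollow at point size so they are
distinguishable from true zeros. Labels are separate text nodes and no
collision avoidance is attempted — the documents are meant to be adjusted in
an SVG editor.

## Synthetic data

The generator plants clusters (anchor, gene count, intra-gap range) and
isolated genes (kept at least `isolation_gap` from every other gene on their
chromosome) on named chromosomes, with uniformly drawn gene lengths and ±1
strands. Expression emulates a stage-resolved profile: each planted cluster
shares one "hot" stage with values ~ N(8, 1) over |N(0.5, 0.2)| background,
and a configurable fraction of cells is set missing. The construction
guarantees that any D with max intra-gap ≤ D < isolation gap recovers exactly
the planted clusters, which is the recovery property the tests and the
acceptance script measure.

What the generator does **not** emulate: overlapping or nested genes, tandem
duplications, chromosome-scale density gradients, correlated microarray
noise, or probe-level artifacts. Passing the recovery tests therefore shows
the algorithm and pipeline are correct, not that any particular biological
dataset will cluster.

## Problem sizes and numerics

The acceptance script runs 300 random oracle instances (≤ 50 genes × ≤ 4
chromosomes), 60 random synthetic specs, 100 format round-trips, and one
genome-scale run of 400 planted clusters plus 2000 isolated genes (≈ 4000
genes) with a 20-run randomization baseline — a scale chosen to mirror a
gene-dense eukaryotic chromosome set while completing in seconds. All
randomness flows from the `--seed` argument through numpy `SeedSequence`
spawning, so every run is bit-reproducible and independent of execution
order. Coordinates are exact integers throughout; the only floating-point
computation is the t-test (agreement with an independent reference is tested
at 1e-10) and the SVG geometry (formatted at fixed decimal precision, making
renders byte-identical across runs).

## Known limitations

- Start-only distance (see above) and a single global threshold.
- Keep-first duplicate handling is a safety net, not probe aggregation.
- The per-cluster local-gene-density significance test is out of scope; the
  baseline is global random sampling from the pool.
- No BED/GFF import; positions enter via the delimited Biomart-style table.
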