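# Methods

## Model

A *comparison* is a treatment-vs-reference contrast carrying, per gene,
a log₂ fold-change and a p-value assumed already adjusted for multiple
testing upstream (e.g. by Benjamini–Hochberg); the package performs no
p-value computation or correction of its own. A *scorecard* for an
ordered pair of comparisons (x, y) classifies every gene present in both
by the band of each coordinate — central (|v| < t_low), moderate
(t_low ≤ |v| < t_high), extreme (|v| ≥ t_high) — into a quadrant
(signs of x and y) and a region letter (A, B, C, D, E, M, S, R; see the
README table). The central/central cell is never reported. A study's
*collection* is the set of scorecards for all unordered comparison
pairs, each pair emitted once with the earlier comparison of the input
list on the x-axis (input order, not lexicographic, so the user controls
axis orientation reproducibly).

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `t_low` | log₂ fold-change | 2 | inner threshold (4-fold change) |
| `t_high` | log₂ fold-change | 3 | outer threshold; may be given as `t_low × factor` (thresholds (2, 3) ≡ factor 1.5, (2, 4) ≡ factor 2); unused/omitted in fourway mode |
| `alpha` | probability | 0.05 | significance level; `p ≤ alpha` passes |
| `mode` | — | `full` | `fourway` / `standard` (A–E) / `full` (A–R) |
| `significance_policy` | — | `non_central_axes` | which axes must be significant |
| `pseudocount` | expression units | 1.0 | added to both numerator and denominator when deriving log₂ fold-changes from a condition × gene expression table (standard practice for FPKM-scale data) |
| fold-change cap | log₂ fold-change | ±20 | non-finite or larger inputs are clamped and flagged in the load report, keeping classification total without silently inventing data |

## Conventions and tie-breaks

- **Boundaries are outward-inclusive**: |v| = t_low is moderate,
  |v| = t_high is extreme, and p = alpha passes. Bands are half-open, so
  the classification is total and deterministic.
- **Zero coordinates count as positive** for quadrant assignment; this
  only matters for genes lying exactly on an axis (regions D/E/S/R).
- **Letter/axis convention**: the x-dominant letters are C
  (extreme-x/moderate-y), D (extreme-x/central-y) and S
  (moderate-x/central-y); B, E, R are their y-dominant mirrors. D vs. E
  is fixed by the convention that a gene markedly changed on x and flat
  on y is D. Because published figures sometimes draw the mirrored
  convention, `ScorecardConfig(swap_letter_axes=True)` flips B↔C, D↔E,
  S↔R.
- **Significance policy**: the default `non_central_axes` requires
  p ≤ alpha on every axis whose band is moderate or extreme and exempts
  central axes. A `both_axes` rule would empty the one-sided regions D,
  E, S, R — a flat axis essentially never has a significant p — so the
  stricter and looser (`either_axis`) rules are offered but not default.
  A missing p-value always fails its axis test (conservative). The same
  machinery applies in fourway mode.
- **Drop accounting**: per scorecard, genes are counted under
  `missing_partner` (present in only one comparison; no imputation is
  attempted), `not_reported` (central on both axes, or masked by the
  mode, e.g. M/S/R under `standard`), or `not_significant`. Entries plus
  drops always equal the size of the union of the two gene sets.
- **Difference ranking** uses the absolute difference of the two log₂
  fold-changes, |x − y| (a defensible reading of "expression
  difference" on the log scale), sorted descending with ties broken by
  collection pair order then gene id.
- **Keyword frequencies** use case-insensitive substring containment,
  counted per scorecard entry (a gene reported on five scorecards
  contributes its annotation five times), with the total number of
  scanned annotation strings reported alongside.
- **Occurrence counting** counts scorecards, not regions; the
  per-scorecard (pair, cell) breakdown is returned alongside for
  region-wise summaries.

## Synthetic data generator

`generate_fixture` emulates the tabular output of an upstream DE
pipeline for a multi-condition study: a set of comparisons over a shared
gene universe with planted signal. Coordinates of planted genes are
drawn at the midpoint of their target band ± a jitter strictly smaller
than half the narrowest band width, so no draw can cross a boundary and
recovery is exact by construction rather than statistical. Planted genes
receive p ~ U(0, 0.8α) on non-central axes and p ~ U(1.2α, ·) on central
axes; noise genes are central (|log₂FC| ≤ 0.4·t_low) and non-significant
everywhere, so a false report is impossible under any mode or policy.
Planted genes exist only in their target pair's two comparisons, making
each structurally exclusive; `recurrent_genes` adds genes that are
extreme and significant in every comparison and hence appear on every
scorecard. `generate_longitudinal_fixture` gives each time point its own
comparison pair and plants a scripted region per time, emulating
time-course designs.

What the generator does **not** emulate: read-count noise, library-size
and dispersion effects, correlated fold-changes across comparisons
sharing a control, p-values that covary with effect size, or annotation
vocabularies. Passing the planted-recovery tests therefore demonstrates
the correctness of the classification, filtering and aggregation logic —
not robustness to upstream estimation error, which is out of scope
because inputs are taken as the upstream pipeline's finished estimates.
Default sizes (hundreds to thousands of noise genes, a handful of
planted genes per cell) mirror the qualitative scale of real bacterial
transcriptomes while keeping the full suite fast; the acceptance script
uses 5 genes per cell per scorecard and 2,000 noise genes.

## Numerical and serialization choices

- Derived pairwise fold-changes are computed as
  log₂(a + pc) − log₂(b + pc), not log₂ of the ratio, so swapping the
  two conditions negates every value exactly.
- The JSON archive (schema version 1.0) serializes floats with Python's
  shortest round-trip representation; export→import is an identity on
  all fields. Unknown schema versions and structurally invalid elements
  raise errors naming the first offending element. The provenance
  timestamp is optional and omitted by default so identical runs produce
  byte-identical archives.
- Presentation tables (CSV/XLSX) round floats to 9 decimals: XLSX stores
  at most 15 significant digits, and rounding keeps the two formats
  cell-identical. The archive, not the tables, is the lossless store.
- Figures return a machine-checkable manifest (marker/dot/bar
  coordinates, colors, counts), so tests never inspect pixels. Label
  decluttering uses seeded deterministic offsets (default seed 0). The
  radial overview uses a linear radial scale with the zero-fold-change
  ring drawn explicitly. Region colors default to a colorblind-safe
  palette and are user-overridable; all eight letters must be covered.

## Known limitations

- Genes present in one comparison but not the other are dropped (with
  accounting), never imputed.
- The fourway mode applies the same significance machinery as the other
  modes; a variant with no significance filtering is not provided.
- No automatic threshold selection, enrichment analysis, clustering, or
  interactive graphics; the scorecard is positioned as an alternative to
  the heatmap+dendrogram view, not an implementation of it.
- Problem sizes in the test and acceptance runs (4–6 comparisons,
  thousands of genes, 20 invariant seeds) were chosen as the smallest
  scales at which every code path and all 32 cells are exercised; the
  library itself has no size limits beyond memory.
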