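# descorecard

Scorecard synthesis of differential-expression results across multiple
experimental conditions.

## The problem

Differential-expression (DE) studies with more than two conditions —
several antibiotics against one untreated biofilm control, several
carbon sources, several biomaterials sampled over time — produce one
volcano plot per contrast and quickly overwhelm visual inspection. A
four-way plot helps by plotting two treatment-vs-control log₂
fold-changes against each other, but it uses a single threshold, is not
filtered by statistical significance, and offers no way to merge
information across the many pairwise views.

The *scorecard* extends the four-way plot. For a pair of comparisons
with per-gene log₂ fold-changes (x, y), two thresholds
0 < t_low < t_high split each axis into three bands

- central: |v| < t_low
- moderate: t_low ≤ |v| < t_high
- extreme: |v| ≥ t_high

and the 3×3 band grid labels each Cartesian quadrant with lettered
regions of interest:

| x band | y band | region |
|---|---|---|
| extreme | extreme | **A** |
| extreme | moderate | **C** |
| moderate | extreme | **B** |
| extreme | central | **D** |
| central | extreme | **E** |
| moderate | moderate | **M** |
| moderate | central | **S** |
| central | moderate | **R** |

Genes central on both axes are never reported. Three modes control the
detail level: `fourway` (single threshold, quadrant only), `standard`
(regions A–E, at least one extreme axis), `full` (all eight letters).
A significance filter keeps only genes whose relevant axes have
(upstream-adjusted) p ≤ α; by default only the non-central axes are
tested, so one-sided regions like D and E stay populable.

On top of single scorecards, the package aggregates a whole study — all
n(n−1)/2 pairwise scorecards of n comparisons — into region-count
matrices, per-gene occurrence counts, exclusive-gene lists (genes
reported on exactly one scorecard), rankings by |x−y| expression
difference, annotation-keyword frequencies, and longitudinal region
tracks, with CSV/XLSX/JSON/log exports and four figure types.

## Worked example

`examples/01_classify_one_pair.py` scores four genes shared by two
drug-vs-control comparisons with thresholds (2, 3) and α = 0.05:

```
scorecard drugA_vs_ctrl (x) vs drugB_vs_ctrl (y), mode=full
  geneUp    x=+3.60 y=+0.80 -> Q1 D
  geneBoth  x=+3.20 y=+4.10 -> Q1 A
  geneMild  x=+2.40 y=-2.20 -> Q4 M
dropped: {'missing_partner': 0, 'not_reported': 1, 'not_significant': 0}
```

`geneUp` changes markedly under drug A only (extreme x, central y →
region D); `geneBoth` is extreme under both drugs (region A); `geneMild`
changes moderately in opposite directions (quadrant Q4, region M, only
reported by the full scorecard); the fourth gene is central on both axes
and is dropped as not reported. The other examples cover study-level
aggregation (`02`), longitudinal region tracking (`03`) and
archives/figures (`04`); each prints the numbers it computes.

The same pipeline is scriptable from the shell:

```bash
descorecard fixture --out study.csv --seed 42 --conditions 4
descorecard run --input study.csv --gene-col gene \
  --comparison T01_vs_ctrl:T01_vs_ctrl__log2fc:T01_vs_ctrl__p \
  --comparison T02_vs_ctrl:T02_vs_ctrl__log2fc:T02_vs_ctrl__p \
  --t-low 2 --t-high 3 --alpha 0.05 --mode full \
  --out results/ --formats csv,json,log --plots heatmap,radial
```

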