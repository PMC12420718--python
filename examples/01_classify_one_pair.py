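"""Classify genes on a single scorecard.

Builds two tiny treatment-vs-control comparisons by hand, scores the
shared genes with thresholds (2, 3) and alpha = 0.05, and prints each
reported gene's quadrant and region of interest.
"""

from descorecard import (
    Comparison,
    GeneRecord,
    ScorecardConfig,
    build_scorecard,
)

treated_x = Comparison("drugA_vs_ctrl", {
    "geneUp": GeneRecord("geneUp", 3.6, 0.004),      # extreme up on x
    "geneBoth": GeneRecord("geneBoth", 3.2, 0.010),  # extreme on both axes
    "geneMild": GeneRecord("geneMild", 2.4, 0.030),  # moderate on both
    "geneFlat": GeneRecord("geneFlat", 0.3, 0.600),  # central everywhere
})
treated_y = Comparison("drugB_vs_ctrl", {
    "geneUp": GeneRecord("geneUp", 0.8, 0.700),
    "geneBoth": GeneRecord("geneBoth", 4.1, 0.002),
    "geneMild": GeneRecord("geneMild", -2.2, 0.020),
    "geneFlat": GeneRecord("geneFlat", 0.1, 0.900),
})

config = ScorecardConfig(t_low=2.0, t_high=3.0, alpha=0.05, mode="full")
sc = build_scorecard(treated_x, treated_y, config)

print(f"scorecard {sc.x_name} (x) vs {sc.y_name} (y), mode={config.mode}")
for e in sc.entries:
    print(f"  {e.gene_id:9s} x={e.x_fc:+.2f} y={e.y_fc:+.2f} -> {e.assignment.label}")
print(f"dropped: {sc.dropped}")

# geneUp changes only on the x axis (region D); geneBoth is extreme on
# both (region A); geneMild is moderate with opposite signs (Q4, region
# M); geneFlat is central on both axes and is not reported.
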