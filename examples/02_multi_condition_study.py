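"""Synthesize a whole multi-condition study.

Generates a planted synthetic study (4 comparisons -> 6 scorecards),
builds every pairwise scorecard, and prints the collection-level
aggregates: region counts, gene occurrences, exclusive genes and the
largest between-condition expression differences.
"""

from descorecard import (
    FixtureSpec,
    ScorecardCollection,
    ScorecardConfig,
    build_scorecard,
    enumerate_scorecard_pairs,
    exclusive_genes,
    gene_occurrence,
    generate_fixture,
    keyword_frequency,
    rank_by_difference,
    region_count_matrix,
)

spec = FixtureSpec(n_comparisons=4, genes_per_cell=1, noise_genes=300,
                   recurrent_genes=2, seed=42)
result = generate_fixture(spec)

config = ScorecardConfig(t_low=2.0, t_high=3.0, alpha=0.05, mode="full")
cards = [build_scorecard(a, b, config)
         for a, b in enumerate_scorecard_pairs(result.comparisons)]
coll = ScorecardCollection(cards, study_label="demo")

print(f"{len(coll)} scorecards from {spec.n_comparisons} comparisons")

mat = region_count_matrix(coll)
print("\nregion counts, first scorecard row (non-zero cells):")
row = mat.iloc[0]
print("  " + ", ".join(f"{c}={v}" for c, v in row.items() if v))

occ = gene_occurrence(coll)
top = sorted(occ.items(), key=lambda kv: (-kv[1].count, kv[0]))[:3]
print("\nmost recurrent genes (scorecards reporting them):")
for gid, rec in top:
    print(f"  {gid}: {rec.count}")

excl = exclusive_genes(coll)
print(f"\nexclusive genes (reported on exactly one scorecard): {len(excl)}")
x, y, q, r, gid = excl[0]
print(f"  e.g. {gid} on ({x}, {y}) in {q.value} {r.value}")

print("\ntop 3 between-condition differences:")
for row in rank_by_difference(coll, top_n=3):
    print(f"  {row.gene_id}: |{row.x_fc:+.2f} - {row.y_fc:+.2f}| "
          f"= {row.difference:.2f} on ({row.x_comparison}, {row.y_comparison})")

counts, total = keyword_frequency(coll, ["planted", "recurrent"])
print(f"\nkeyword counts over {total} scanned annotations: {counts}")
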