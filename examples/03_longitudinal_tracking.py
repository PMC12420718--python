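"""Track a gene's region of interest over a time course.

Emulates a longitudinal design (one scorecard per sampling time) with a
scripted drift — a gene mildly expressed at the first time point that
becomes extremely overexpressed afterwards — and recovers the script
with track_regions_over_series.
"""

from descorecard import (
    Region,
    ScorecardCollection,
    ScorecardConfig,
    build_scorecard,
    generate_longitudinal_fixture,
    track_regions_over_series,
)

times = ["t03", "t06", "t12", "t24", "t60"]
scripts = {
    "early_responder": [Region.M, Region.A, Region.A, Region.A, Region.A],
    "late_dropout": [Region.D, Region.D, Region.D, None, None],
}
comparisons, series, _truth = generate_longitudinal_fixture(times, scripts)

config = ScorecardConfig(t_low=2.0, t_high=3.0, alpha=0.05, mode="full")
by_name = {c.name: c for c in comparisons}
cards = [build_scorecard(by_name[x], by_name[y], config) for x, y in series]
coll = ScorecardCollection(cards, study_label="time-course")

for gene in scripts:
    track = track_regions_over_series(coll, gene, series)
    labels = [a.label if a.is_reported else "-" for a in track]
    print(f"{gene:16s} " + "  ".join(f"{t}:{l}" for t, l in zip(times, labels)))

# early_responder moves from the moderate/moderate cell (M) at t=3 to
# the extreme/extreme cell (A) from t=6 on; late_dropout is reported in
# the one-sided region D until it disappears from the data at t=24.
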