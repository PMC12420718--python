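import pytest

from descorecard import (
    NOT_REPORTED,
    Comparison,
    GeneRecord,
    Quadrant,
    Region,
    ScorecardCollection,
    ScorecardConfig,
    build_scorecard,
    exclusive_genes,
    gene_occurrence,
    generate_longitudinal_fixture,
    keyword_frequency,
    merged_overview,
    rank_by_difference,
    region_count_matrix,
    track_regions_over_series,
)


def _comp(name, genes):
    return Comparison(name, {g: GeneRecord(g, fc, p, note)
                             for g, fc, p, note in genes})


@pytest.fixture(scope="module")
def small_collection():
    """Three comparisons, hand-built so every aggregate is checkable by eye.

    shared: extreme+significant everywhere -> on all 3 scorecards (Q1 A)
    lonely: present only in A and B, central on B -> only on (A, B) as Q1 D
    gap_*:  two genes (A and B only) with distinct |x - y| gaps
    """
    a = _comp("A", [
        ("shared", 4.0, 0.01, "ABC transporter permease"),
        ("lonely", 3.6, 0.01, "phenol-soluble modulin"),
        ("gap_big", 6.92, 0.01, None),
        ("gap_small", 3.2, 0.01, None),
    ])
    b = _comp("B", [
        ("shared", 3.8, 0.02, "ABC transporter permease"),
        ("lonely", 0.5, 0.8, None),
        ("gap_big", 1.7, 0.03, None),
        ("gap_small", 3.1, 0.02, None),
    ])
    c = _comp("C", [
        ("shared", 4.2, 0.01, "ABC transporter permease"),
    ])
    cfg = ScorecardConfig(t_low=2, t_high=3, alpha=0.05, mode="full")
    cards = [build_scorecard(x, y, cfg)
             for x, y in [(a, b), (a, c), (b, c)]]
    return ScorecardCollection(cards, study_label="hand")


class TestRegionCountMatrix:
    def test_counts_match_hand_classification(self, small_collection):
        mat = region_count_matrix(small_collection)
        ab = mat.loc[("A", "B")]
        assert ab["Q1 A"] == 2        # shared (4.0, 3.8), gap_small (3.2, 3.1)
        assert ab["Q1 D"] == 2        # lonely (3.6, 0.5), gap_big (6.92, 1.7)
        assert ab.sum() == len(small_collection.by_pair[("A", "B")])

    def test_columns_complete_and_ordered(self, small_collection):
        mat = region_count_matrix(small_collection)
        expected = [f"{q} {r}" for q in ("Q1", "Q2", "Q3", "Q4")
                    for r in "ABCDEMSR"]
        assert list(mat.columns) == expected

    def test_grand_total_conservation(self, small_collection, planted_collection):
        for coll in (small_collection, planted_collection):
            mat = region_count_matrix(coll)
            total_entries = sum(len(sc) for sc in coll)
            assert mat.to_numpy().sum() == total_entries
            assert sum(rec.count for rec in gene_occurrence(coll).values()) \
                == total_entries

    def test_row_sums_equal_entry_counts(self, planted_collection):
        mat = region_count_matrix(planted_collection)
        for sc in planted_collection:
            assert mat.loc[sc.pair_key].sum() == len(sc)


class TestGeneOccurrence:
    def test_counts_scorecards_not_regions(self, small_collection):
        occ = gene_occurrence(small_collection)
        assert occ["shared"].count == 3
        assert occ["lonely"].count == 1
        assert "never_reported" not in occ

    def test_counts_bounded_by_collection_size(self, planted_collection):
        occ = gene_occurrence(planted_collection)
        n = len(planted_collection)
        assert all(1 <= rec.count <= n for rec in occ.values())

    def test_recurrent_genes_on_every_scorecard(self, planted_fixture,
                                                planted_collection):
        _, result = planted_fixture
        occ = gene_occurrence(planted_collection)
        recurrent = [g for g in result.truth if g.startswith("recur_")]
        assert recurrent
        for g in recurrent:
            assert occ[g].count == len(planted_collection)


class TestExclusiveGenes:
    def test_exactly_the_count_one_genes(self, small_collection):
        rows = exclusive_genes(small_collection)
        symbols = [r[4] for r in rows]
        assert "lonely" in symbols and "shared" not in symbols
        lonely = next(r for r in rows if r[4] == "lonely")
        assert lonely[:2] == ("A", "B")
        assert (lonely[2], lonely[3]) == (Quadrant.Q1, Region.D)

    def test_partition_with_multiply_reported(self, planted_collection):
        occ = gene_occurrence(planted_collection)
        excl = {r[4] for r in exclusive_genes(planted_collection)}
        multi = {g for g, rec in occ.items() if rec.count >= 2}
        assert excl | multi == set(occ)
        assert excl.isdisjoint(multi)

    def test_single_scorecard_rejected(self, small_collection):
        solo = ScorecardCollection([small_collection.scorecards[0]])
        with pytest.raises(ValueError):
            exclusive_genes(solo)

    def test_sorted_by_pair_then_region_then_gene(self, planted_collection):
        rows = exclusive_genes(planted_collection)
        pair_rank = {sc.pair_key: i for i, sc in enumerate(planted_collection)}
        keys = [(pair_rank[(r[0], r[1])], r[2].value, "ABCDEMSR".index(r[3].value),
                 r[4]) for r in rows]
        assert keys == sorted(keys)


class TestRankByDifference:
    def test_worked_difference(self, small_collection):
        rows = rank_by_difference(small_collection, top_n=30)
        top = rows[0]
        assert top.gene_id == "gap_big"
        assert top.difference == pytest.approx(6.92 - 1.7)

    def test_descending_and_recomputable(self, planted_collection):
        rows = rank_by_difference(planted_collection, top_n=None)
        diffs = [r.difference for r in rows]
        assert diffs == sorted(diffs, reverse=True)
        for r in rows:
            assert r.difference == abs(r.x_fc - r.y_fc)

    def test_truncation(self, planted_collection):
        rows = rank_by_difference(planted_collection, top_n=30)
        assert len(rows) == 30

    def test_equal_coordinates_rank_last(self):
        a = _comp("A", [("flat", 4.0, 0.01, None), ("steep", 5.0, 0.01, None)])
        b = _comp("B", [("flat", 4.0, 0.01, None), ("steep", 3.0, 0.01, None)])
        coll = ScorecardCollection(
            [build_scorecard(a, b, ScorecardConfig(t_low=2, t_high=3))]
        )
        rows = rank_by_difference(coll)
        assert [r.gene_id for r in rows] == ["steep", "flat"]
        assert rows[-1].difference == 0.0


class TestKeywordFrequency:
    def test_counts_per_entry_with_repetition(self, small_collection):
        counts, total = keyword_frequency(
            small_collection, ["ABC transporter", "modulin", "kinase"]
        )
        # "shared" is reported on 3 scorecards, its annotation scanned 3x
        assert counts["ABC transporter"] == 3
        assert counts["modulin"] == 1
        assert counts["kinase"] == 0
        assert total == 4  # 3x shared + 1x lonely annotations

    def test_case_insensitive(self, small_collection):
        counts, _ = keyword_frequency(small_collection, ["abc TRANSPORTER"])
        assert counts["abc TRANSPORTER"] == 3

    def test_empty_keyword_rejected(self, small_collection):
        with pytest.raises(ValueError):
            keyword_frequency(small_collection, [""])

    def test_empty_keyword_list_still_reports_total(self, small_collection):
        counts, total = keyword_frequency(small_collection, [])
        assert counts == {} and total == 4


class TestTrackRegionsOverSeries:
    def test_scripted_drift_recovered(self):
        script = {"g_drift": [Region.M, Region.A, Region.A],
                  "g_gone": [Region.S, None, Region.S]}
        comps, keys, _ = generate_longitudinal_fixture(
            ["t03", "t06", "t12"], script)
        cfg = ScorecardConfig(t_low=2, t_high=3)
        by_name = {c.name: c for c in comps}
        cards = [build_scorecard(by_name[x], by_name[y], cfg) for x, y in keys]
        coll = ScorecardCollection(cards)
        track = track_regions_over_series(coll, "g_drift", keys)
        assert [a.region for a in track] == [Region.M, Region.A, Region.A]
        track2 = track_regions_over_series(coll, "g_gone", keys)
        assert [a.region for a in track2] == [Region.S, None, Region.S]
        assert track2[1] is NOT_REPORTED

    def test_absent_gene_all_not_reported(self, small_collection):
        keys = [sc.pair_key for sc in small_collection]
        track = track_regions_over_series(small_collection, "ghost", keys)
        assert len(track) == len(keys)
        assert all(a is NOT_REPORTED for a in track)

    def test_unknown_pair_key_rejected(self, small_collection):
        with pytest.raises(KeyError):
            track_regions_over_series(small_collection, "shared", [("A", "Z")])

    def test_agrees_with_per_scorecard_lookup(self, planted_collection):
        keys = [sc.pair_key for sc in planted_collection]
        gid = next(iter(gene_occurrence(planted_collection)))
        track = track_regions_over_series(planted_collection, gid, keys)
        for sc, a in zip(planted_collection, track):
            entry = sc.get(gid)
            assert a == (entry.assignment if entry else NOT_REPORTED)


class TestMergedOverview:
    def test_groups_mirror_scorecards(self, small_collection):
        groups = merged_overview(small_collection)
        assert len(groups) == len(small_collection)
        for sc in small_collection:
            assert [e.gene_id for e in groups[sc.pair_key]] \
                == [e.gene_id for e in sc.entries]

    def test_coordinates_pass_through(self, small_collection):
        groups = merged_overview(small_collection)
        e = next(e for e in groups[("A", "B")] if e.gene_id == "gap_big")
        assert (e.x_fc, e.y_fc) == (6.92, 1.7)

    def test_empty_scorecard_keeps_its_group(self):
        a = _comp("A", [("g", 0.1, 0.9, None)])
        b = _comp("B", [("g", 0.2, 0.9, None)])
        coll = ScorecardCollection([build_scorecard(a, b, ScorecardConfig())])
        groups = merged_overview(coll)
        assert groups == {("A", "B"): []}


class TestCollectionInvariants:
    def test_mixed_configs_rejected(self, small_collection):
        other = build_scorecard(
            _comp("P", [("g", 3.0, 0.01, None)]),
            _comp("Q", [("g", 3.0, 0.01, None)]),
            ScorecardConfig(t_low=1, t_high=4),
        )
        with pytest.raises(ValueError):
            ScorecardCollection(small_collection.scorecards + [other])

    def test_duplicate_pairs_rejected(self, small_collection):
        sc = small_collection.scorecards[0]
        with pytest.raises(ValueError):
            ScorecardCollection([sc, sc])
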