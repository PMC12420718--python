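"""Collection-level synthesis across many scorecards.

A study's scorecards (one per comparison pair, all sharing one config)
are merged here into region-count matrices, per-gene occurrence counts,
exclusive-gene lists, difference rankings, annotation-keyword
frequencies and longitudinal region tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .classify import (
    NOT_REPORTED,
    Quadrant,
    Region,
    RegionAssignment,
    Scorecard,
    ScorecardEntry,
)

__all__ = [
    "ScorecardCollection",
    "GeneOccurrence",
    "DifferenceRow",
    "region_count_matrix",
    "gene_occurrence",
    "exclusive_genes",
    "rank_by_difference",
    "keyword_frequency",
    "track_regions_over_series",
    "merged_overview",
]

PairKey = tuple[str, str]

_REGION_ORDER = [Region.A, Region.B, Region.C, Region.D,
                 Region.E, Region.M, Region.S, Region.R]
_QUADRANT_ORDER = [Quadrant.Q1, Quadrant.Q2, Quadrant.Q3, Quadrant.Q4]


@dataclass
class ScorecardCollection:
    """Ordered set of scorecards for one study."""

    scorecards: list[Scorecard]
    study_label: str = "study"
    #: comparison name -> ordinal time, for longitudinal studies
    time_key: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        keys = [sc.pair_key for sc in self.scorecards]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (x, y) scorecard pairs in collection")
        configs = {sc.config.key_fields() for sc in self.scorecards}
        if len(configs) > 1:
            raise ValueError(
                "all scorecards of a collection must share thresholds, "
                "alpha, mode and significance policy"
            )

    @property
    def by_pair(self) -> dict[PairKey, Scorecard]:
        return {sc.pair_key: sc for sc in self.scorecards}

    @property
    def config(self):
        if not self.scorecards:
            raise ValueError("empty collection has no config")
        return self.scorecards[0].config

    def __len__(self) -> int:
        return len(self.scorecards)

    def __iter__(self):
        return iter(self.scorecards)


def _cell_label(assignment: RegionAssignment) -> str:
    return assignment.label


def _column_order(coll: ScorecardCollection) -> list[str]:
    """Deterministic Q1..Q4 x A..R column order for the collection's mode."""
    if coll.scorecards and coll.config.mode == "fourway":
        return [q.value for q in _QUADRANT_ORDER]
    return [f"{q.value} {r.value}" for q in _QUADRANT_ORDER for r in _REGION_ORDER]


def region_count_matrix(coll: ScorecardCollection) -> pd.DataFrame:
    """Gene counts per scorecard row and (quadrant, region) column.

    Rows are indexed by the (x, y) comparison-name pair; every column of
    the deterministic Q1..Q4 x A..R grid is present, zero-filled, and a
    row sums to that scorecard's entry count.
    """
    if not coll.scorecards:
        raise ValueError("region_count_matrix needs a non-empty collection")
    cols = _column_order(coll)
    index = pd.MultiIndex.from_tuples(
        [sc.pair_key for sc in coll], names=["x_comparison", "y_comparison"]
    )
    mat = pd.DataFrame(0, index=index, columns=cols, dtype=int)
    for sc in coll:
        for e in sc.entries:
            mat.loc[sc.pair_key, _cell_label(e.assignment)] += 1
    return mat


@dataclass
class GeneOccurrence:
    """Where (and how often) one gene is reported across a collection."""

    count: int
    places: list[tuple[PairKey, RegionAssignment]] = field(default_factory=list)


def gene_occurrence(coll: ScorecardCollection) -> dict[str, GeneOccurrence]:
    """Per gene, the number of scorecards reporting it and the cells.

    Counts scorecards (a gene reported on 65 of 105 scorecards has count
    65); genes reported nowhere are omitted.  The ``places`` list gives
    the per-scorecard (pair, assignment) breakdown for region-wise bar
    plots.
    """
    occ: dict[str, GeneOccurrence] = {}
    for sc in coll:
        for e in sc.entries:
            rec = occ.setdefault(e.gene_id, GeneOccurrence(0))
            rec.count += 1
            rec.places.append((sc.pair_key, e.assignment))
    return occ


def exclusive_genes(
    coll: ScorecardCollection,
) -> list[tuple[str, str, Quadrant, Optional[Region], str]]:
    """Genes reported in exactly one scorecard of the collection.

    Returns (x_comparison, y_comparison, quadrant, region, gene_id)
    tuples sorted by pair order in the collection, then region letter,
    then gene id.  Requires at least two scorecards — exclusivity is
    meaningless otherwise.
    """
    if len(coll) < 2:
        raise ValueError("exclusive_genes needs >= 2 scorecards")
    pair_rank = {sc.pair_key: i for i, sc in enumerate(coll)}
    region_rank = {r: i for i, r in enumerate(_REGION_ORDER)}
    quadrant_rank = {q: i for i, q in enumerate(_QUADRANT_ORDER)}
    rows = []
    for gid, rec in gene_occurrence(coll).items():
        if rec.count == 1:
            (pair, assignment) = rec.places[0]
            rows.append((pair[0], pair[1], assignment.quadrant, assignment.region, gid))
    rows.sort(
        key=lambda r: (
            pair_rank[(r[0], r[1])],
            quadrant_rank[r[2]],
            region_rank.get(r[3], len(region_rank)),
            r[4],
        )
    )
    return rows


@dataclass(frozen=True)
class DifferenceRow:
    x_comparison: str
    y_comparison: str
    quadrant: Quadrant
    region: Optional[Region]
    gene_id: str
    x_fc: float
    y_fc: float

    @property
    def difference(self) -> float:
        return abs(self.x_fc - self.y_fc)


def rank_by_difference(
    coll: ScorecardCollection, top_n: Optional[int] = None
) -> list[DifferenceRow]:
    """Reported genes ranked by |x_fc - y_fc|, largest first.

    The difference is the absolute gap between the two log2
    fold-changes.  Ties break by collection pair order, then gene id;
    ``top_n`` truncates the ranking.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be a positive integer")
    pair_rank = {sc.pair_key: i for i, sc in enumerate(coll)}
    rows = [
        DifferenceRow(
            sc.x_name, sc.y_name, e.assignment.quadrant, e.assignment.region,
            e.gene_id, e.x_fc, e.y_fc,
        )
        for sc in coll
        for e in sc.entries
    ]
    rows.sort(
        key=lambda r: (
            -r.difference,
            pair_rank[(r.x_comparison, r.y_comparison)],
            r.gene_id,
        )
    )
    return rows[:top_n] if top_n is not None else rows


def keyword_frequency(
    coll: ScorecardCollection, keywords: Sequence[str]
) -> tuple[dict[str, int], int]:
    """Occurrences of each keyword in the reported genes' annotations.

    Matching is case-insensitive substring containment, counted per
    scorecard entry (a gene reported on several scorecards contributes
    its annotation once per scorecard).  Returns the per-keyword counts
    and the total number of annotation strings scanned.
    """
    if any(not k for k in keywords):
        raise ValueError("keywords must be non-empty strings")
    notes = [
        e.annotation
        for sc in coll
        for e in sc.entries
        if e.annotation is not None
    ]
    lowered = [n.lower() for n in notes]
    counts = {
        k: sum(1 for n in lowered if k.lower() in n) for k in keywords
    }
    return counts, len(notes)


def track_regions_over_series(
    coll: ScorecardCollection, gene_id: str, series: Sequence[PairKey]
) -> list[RegionAssignment]:
    """Region of one gene along an ordered series of scorecards.

    Useful for longitudinal designs (e.g. shifts from moderate to
    extreme expression over sampling times).  Positions where the gene
    is not reported yield :data:`NOT_REPORTED`.
    """
    by_pair = coll.by_pair
    unknown = [k for k in series if tuple(k) not in by_pair]
    if unknown:
        raise KeyError(f"unknown scorecard pair key(s): {unknown}")
    track = []
    for key in series:
        entry = by_pair[tuple(key)].get(gene_id)
        track.append(entry.assignment if entry is not None else NOT_REPORTED)
    return track


def merged_overview(
    coll: ScorecardCollection,
) -> dict[PairKey, list[ScorecardEntry]]:
    """Reported entries grouped by pair, for the radial merged plot.

    Every scorecard keeps a group (possibly empty, so its radius is
    still drawn); entry coordinates pass through unchanged.
    """
    return {sc.pair_key: list(sc.entries) for sc in coll}
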