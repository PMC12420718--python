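"""Synthetic comparison tables with genes planted in known scorecard cells.

Real studies of this kind need external downloads; the generator stands
in for them with tables whose classification is known *by construction*:
planted coordinates are drawn at the midpoint of their target band plus
a jitter strictly smaller than the distance to the nearest band
boundary, so recovery is an exact test, not a statistical one.

Three gene populations are emitted:

* **planted** genes exist only in the two comparisons of their target
  pair, with coordinates inside a chosen (quadrant, region) cell,
  significant p on every non-central axis and non-significant p on
  central axes.  Each is therefore reported on exactly one scorecard
  (structurally exclusive) and recoverable cell-by-cell.
* **recurrent** genes are present, extreme, and significant in every
  comparison: they are reported on every scorecard (region A, Q1).
* **noise** genes are central (|log2FC| well below ``t_low``) and
  non-significant everywhere; they are never reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .classify import (
    REGION_CATEGORIES,
    AxisCategory,
    Quadrant,
    Region,
)
from .comparisons import Comparison, GeneRecord, enumerate_scorecard_pairs

__all__ = [
    "FixtureSpec",
    "FixtureResult",
    "generate_fixture",
    "generate_longitudinal_fixture",
    "ALL_CELLS",
    "cell_is_reported",
]

PairKey = tuple[str, str]

#: All 32 (quadrant, region) cells of the full scorecard.
ALL_CELLS: list[tuple[Quadrant, Region]] = [
    (q, r) for q in Quadrant for r in Region
]

_X_SIGN = {Quadrant.Q1: 1.0, Quadrant.Q2: -1.0, Quadrant.Q3: -1.0, Quadrant.Q4: 1.0}
_Y_SIGN = {Quadrant.Q1: 1.0, Quadrant.Q2: 1.0, Quadrant.Q3: -1.0, Quadrant.Q4: -1.0}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-fixture study.

    ``genes_per_cell`` plants that many genes in *every* (quadrant,
    region) cell of *every* enumerated scorecard; a mapping restricts
    the planted cells.  ``jitter`` must stay strictly below half the
    narrowest band width so planted genes cannot cross a boundary.
    """

    n_comparisons: int = 4
    genes_per_cell: Union[int, dict[tuple[Quadrant, Region], int]] = 2
    noise_genes: int = 500
    recurrent_genes: int = 0
    t_low: float = 2.0
    t_high: float = 3.0
    alpha: float = 0.05
    jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_comparisons < 2:
            raise ValueError("need at least 2 comparisons")
        if not 0 < self.t_low < self.t_high:
            raise ValueError("need 0 < t_low < t_high")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        bound = min(self.t_low, self.t_high - self.t_low) / 2.0
        if not 0 <= self.jitter < bound:
            raise ValueError(
                f"jitter {self.jitter} must be < {bound} "
                "(half the narrowest band width) to keep planted genes in-band"
            )

    @property
    def cells(self) -> dict[tuple[Quadrant, Region], int]:
        if isinstance(self.genes_per_cell, int):
            return {cell: self.genes_per_cell for cell in ALL_CELLS}
        return dict(self.genes_per_cell)


@dataclass
class FixtureResult:
    """Generated comparisons plus the planted ground truth."""

    comparisons: list[Comparison]
    #: gene_id -> pair_key -> (quadrant, region); only reported cells listed.
    truth: dict[str, dict[PairKey, tuple[Quadrant, Region]]]
    pair_keys: list[PairKey] = field(default_factory=list)
    noise_gene_ids: list[str] = field(default_factory=list)


def _band_value(
    cat: AxisCategory, spec: FixtureSpec, rng: np.random.Generator
) -> float:
    """Magnitude at the band midpoint +- jitter (extreme band: one band
    width above t_high)."""
    width = spec.t_high - spec.t_low
    mid = {
        AxisCategory.CENTRAL: spec.t_low / 2.0,
        AxisCategory.MODERATE: (spec.t_low + spec.t_high) / 2.0,
        AxisCategory.EXTREME: spec.t_high + width / 2.0,
    }[cat]
    return mid + rng.uniform(-spec.jitter, spec.jitter)


def _p_for(cat: AxisCategory, spec: FixtureSpec, rng: np.random.Generator) -> float:
    """Significant p on non-central axes, non-significant on central ones."""
    if cat is AxisCategory.CENTRAL:
        return float(rng.uniform(spec.alpha * 1.2, min(1.0, spec.alpha * 1.2 + 0.9)))
    return float(rng.uniform(0.0, spec.alpha * 0.8))


def cell_is_reported(region: Region, mode: str, policy: str) -> bool:
    """Whether a planted cell survives a mode mask and significance policy.

    Planted genes carry a non-significant p on central axes, so the
    ``both_axes`` policy can only populate cells whose two axes are
    non-central (A, B, C, M).
    """
    cx, cy = REGION_CATEGORIES[region]
    if mode == "standard" and region in (Region.M, Region.S, Region.R):
        return False
    if policy == "both_axes" and AxisCategory.CENTRAL in (cx, cy):
        return False
    return True


def generate_fixture(spec: FixtureSpec) -> FixtureResult:
    """Build comparisons with genes planted in known scorecard cells.

    Deterministic for a fixed seed.  The returned truth maps each
    planted or recurrent gene to its expected (quadrant, region) per
    scorecard under the full scorecard with the spec's thresholds and
    the default significance policy.
    """
    rng = np.random.default_rng(spec.seed)
    comparisons = [
        Comparison(name=f"T{i + 1:02d}_vs_ctrl") for i in range(spec.n_comparisons)
    ]
    by_name = {c.name: c for c in comparisons}
    pair_keys: list[PairKey] = [
        (a.name, b.name) for a, b in enumerate_scorecard_pairs(comparisons)
    ]
    truth: dict[str, dict[PairKey, tuple[Quadrant, Region]]] = {}

    for pi, (xn, yn) in enumerate(pair_keys):
        for (quadrant, region), count in spec.cells.items():
            cat_x, cat_y = REGION_CATEGORIES[region]
            for k in range(count):
                gid = f"plant_p{pi:02d}_{quadrant.value}{region.value}_{k:03d}"
                x = _X_SIGN[quadrant] * _band_value(cat_x, spec, rng)
                y = _Y_SIGN[quadrant] * _band_value(cat_y, spec, rng)
                by_name[xn].add(
                    GeneRecord(gid, x, _p_for(cat_x, spec, rng),
                               f"planted {quadrant.value} {region.value}")
                )
                by_name[yn].add(
                    GeneRecord(gid, y, _p_for(cat_y, spec, rng),
                               f"planted {quadrant.value} {region.value}")
                )
                truth[gid] = {(xn, yn): (quadrant, region)}

    extreme_mid = spec.t_high + (spec.t_high - spec.t_low) / 2.0
    for k in range(spec.recurrent_genes):
        gid = f"recur_{k:03d}"
        for comp in comparisons:
            v = extreme_mid + rng.uniform(-spec.jitter, spec.jitter)
            comp.add(GeneRecord(gid, v, float(rng.uniform(0, spec.alpha * 0.8)),
                                "recurrent extreme"))
        truth[gid] = {pk: (Quadrant.Q1, Region.A) for pk in pair_keys}

    noise_ids = []
    central_cap = spec.t_low * 0.4
    for k in range(spec.noise_genes):
        gid = f"noise_{k:04d}"
        noise_ids.append(gid)
        for comp in comparisons:
            comp.add(
                GeneRecord(
                    gid,
                    float(rng.uniform(-central_cap, central_cap)),
                    float(rng.uniform(spec.alpha * 1.2, 1.0)),
                    "background",
                )
            )
    return FixtureResult(comparisons, truth, pair_keys, noise_ids)


def generate_longitudinal_fixture(
    time_labels: Sequence[str],
    drift_scripts: dict[str, Sequence[Optional[Region]]],
    spec: Optional[FixtureSpec] = None,
    quadrant: Quadrant = Quadrant.Q1,
) -> tuple[list[Comparison], list[PairKey], dict[str, list[Optional[tuple[Quadrant, Region]]]]]:
    """Time-course fixture: one scorecard per time point, scripted drift.

    ``drift_scripts`` maps a gene id to its region per time point
    (``None`` = absent at that time).  Each time point gets its own pair
    of comparisons, so per-time placements are independent; the series
    of pair keys (in time order) feeds
    :func:`~descorecard.aggregate.track_regions_over_series`, which must
    recover each script exactly.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    for gid, script in drift_scripts.items():
        if len(script) != len(time_labels):
            raise ValueError(f"script for {gid!r} must have {len(time_labels)} steps")
    comparisons: list[Comparison] = []
    pair_keys: list[PairKey] = []
    truth: dict[str, list[Optional[tuple[Quadrant, Region]]]] = {
        g: [] for g in drift_scripts
    }
    for t_idx, label in enumerate(time_labels):
        cx = Comparison(name=f"trtX_{label}")
        cy = Comparison(name=f"trtY_{label}")
        for gid, script in drift_scripts.items():
            region = script[t_idx]
            if region is None:
                truth[gid].append(None)
                continue
            cat_x, cat_y = REGION_CATEGORIES[region]
            x = _X_SIGN[quadrant] * _band_value(cat_x, spec, rng)
            y = _Y_SIGN[quadrant] * _band_value(cat_y, spec, rng)
            cx.add(GeneRecord(gid, x, _p_for(cat_x, spec, rng)))
            cy.add(GeneRecord(gid, y, _p_for(cat_y, spec, rng)))
            truth[gid].append((quadrant, region))
        for k in range(spec.noise_genes):
            gid = f"noise_{label}_{k:04d}"
            for comp in (cx, cy):
                comp.add(
                    GeneRecord(
                        gid,
                        float(rng.uniform(-spec.t_low * 0.4, spec.t_low * 0.4)),
                        float(rng.uniform(spec.alpha * 1.2, 1.0)),
                    )
                )
        comparisons.extend([cx, cy])
        pair_keys.append((cx.name, cy.name))
    return comparisons, pair_keys, truth
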