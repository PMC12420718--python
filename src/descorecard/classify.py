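"""Region-of-interest classification on the pairwise log2-fold-change plane.

A scorecard plots the log2 fold-changes of two comparisons against each
other and partitions the plane with two symmetric thresholds per axis.
Each axis value falls in one of three bands:

* CENTRAL   ``|v| < t_low``   — no relevant change,
* MODERATE  ``t_low <= |v| < t_high`` — mild change,
* EXTREME   ``|v| >= t_high`` — marked change.

The 3x3 grid of band combinations yields eight lettered regions of
interest per quadrant pair (the central/central cell is never reported):

========= ========= ======
x band    y band    region
========= ========= ======
EXTREME   EXTREME   A
EXTREME   MODERATE  C
MODERATE  EXTREME   B
EXTREME   CENTRAL   D
CENTRAL   EXTREME   E
MODERATE  MODERATE  M
MODERATE  CENTRAL   S
CENTRAL   MODERATE  R
========= ========= ======

Three scorecard modes mask this grid: ``fourway`` keeps only the
quadrant (single threshold ``t_low``), ``standard`` reports the regions
with at least one extreme axis (A-E), ``full`` reports all eight
letters.  A per-gene significance filter (p-values are assumed already
multiplicity-adjusted upstream) removes genes whose relevant axes are
not statistically supported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .comparisons import Comparison

__all__ = [
    "AxisCategory",
    "Quadrant",
    "Region",
    "RegionAssignment",
    "NOT_REPORTED",
    "ScorecardConfig",
    "ScorecardEntry",
    "Scorecard",
    "DEFAULT_REGION_COLORS",
    "REGION_CATEGORIES",
    "categorize_axis",
    "assign_quadrant",
    "classify_point",
    "passes_significance",
    "build_scorecard",
]


class AxisCategory(Enum):
    CENTRAL = "central"
    MODERATE = "moderate"
    EXTREME = "extreme"


class Quadrant(Enum):
    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"


class Region(Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    M = "M"
    S = "S"
    R = "R"


#: (x band, y band) -> region letter, x-dominant letters first (C, D, S).
REGION_CATEGORIES: dict[Region, tuple[AxisCategory, AxisCategory]] = {
    Region.A: (AxisCategory.EXTREME, AxisCategory.EXTREME),
    Region.C: (AxisCategory.EXTREME, AxisCategory.MODERATE),
    Region.B: (AxisCategory.MODERATE, AxisCategory.EXTREME),
    Region.D: (AxisCategory.EXTREME, AxisCategory.CENTRAL),
    Region.E: (AxisCategory.CENTRAL, AxisCategory.EXTREME),
    Region.M: (AxisCategory.MODERATE, AxisCategory.MODERATE),
    Region.S: (AxisCategory.MODERATE, AxisCategory.CENTRAL),
    Region.R: (AxisCategory.CENTRAL, AxisCategory.MODERATE),
}

_CATEGORIES_TO_REGION = {cats: r for r, cats in REGION_CATEGORIES.items()}

#: Letter swap applied when the user's source figures use the opposite
#: axis convention (y-dominant letters first).
_AXIS_SWAP = {
    Region.B: Region.C,
    Region.C: Region.B,
    Region.D: Region.E,
    Region.E: Region.D,
    Region.S: Region.R,
    Region.R: Region.S,
    Region.A: Region.A,
    Region.M: Region.M,
}

STANDARD_REGIONS = frozenset({Region.A, Region.B, Region.C, Region.D, Region.E})

# Colorblind-safe palette (Wong); user-overridable per config.
DEFAULT_REGION_COLORS: dict[str, str] = {
    "A": "#D55E00",
    "B": "#0072B2",
    "C": "#009E73",
    "D": "#CC79A7",
    "E": "#56B4E9",
    "M": "#E69F00",
    "S": "#F0E442",
    "R": "#999999",
}


@dataclass(frozen=True)
class RegionAssignment:
    """Placement of one gene: quadrant plus region letter.

    ``region`` is ``None`` either for an unreported gene (then
    ``quadrant`` is also ``None``) or for a reported gene in fourway
    mode, where only the quadrant is meaningful.
    """

    quadrant: Optional[Quadrant] = None
    region: Optional[Region] = None

    def __post_init__(self) -> None:
        if self.region is not None and self.quadrant is None:
            raise ValueError("a region letter requires a quadrant")

    @property
    def is_reported(self) -> bool:
        return self.quadrant is not None

    @property
    def label(self) -> str:
        if not self.is_reported:
            return "NOT_REPORTED"
        if self.region is None:
            return self.quadrant.value
        return f"{self.quadrant.value} {self.region.value}"


NOT_REPORTED = RegionAssignment()

_MODES = ("fourway", "standard", "full")
_POLICIES = ("both_axes", "either_axis", "non_central_axes")


@dataclass(frozen=True)
class ScorecardConfig:
    """Thresholds, significance level and reporting mode for a study.

    Parameters
    ----------
    t_low, t_high
        Inner and outer log2 fold-change thresholds, ``0 < t_low <
        t_high``.  ``t_high`` may be omitted in fourway mode, which uses
        a single threshold.
    alpha
        Significance level; a gene axis passes when ``p <= alpha``.
    mode
        ``fourway`` (quadrant only), ``standard`` (regions A-E) or
        ``full`` (all eight letters).
    significance_policy
        ``both_axes``, ``either_axis`` or ``non_central_axes`` (default:
        every non-central axis must be significant; central axes are
        exempt, which keeps the one-sided regions D/E/S/R populable).
    swap_letter_axes
        Flip the x/y letter convention (B<->C, D<->E, S<->R) to match
        figures drawn with the opposite assignment.
    """

    t_low: float = 2.0
    t_high: Optional[float] = 3.0
    alpha: float = 0.05
    mode: str = "full"
    significance_policy: str = "non_central_axes"
    region_colors: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REGION_COLORS)
    )
    swap_letter_axes: bool = False

    def __post_init__(self) -> None:
        if not (self.t_low > 0 and math.isfinite(self.t_low)):
            raise ValueError(f"t_low must be a positive finite number, got {self.t_low}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.significance_policy not in _POLICIES:
            raise ValueError(
                f"significance_policy must be one of {_POLICIES}, "
                f"got {self.significance_policy!r}"
            )
        if self.t_high is None:
            if self.mode != "fourway":
                raise ValueError(f"t_high is required in {self.mode!r} mode")
        elif not self.t_high > self.t_low:
            raise ValueError(
                f"thresholds must satisfy 0 < t_low < t_high, "
                f"got ({self.t_low}, {self.t_high})"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        missing = set(DEFAULT_REGION_COLORS) - set(self.region_colors)
        if missing:
            raise ValueError(f"region_colors misses letters: {sorted(missing)}")

    @classmethod
    def from_factor(cls, t_low: float, factor: float, **kwargs) -> "ScorecardConfig":
        """Build a config from ``t_low`` and a multiplication factor.

        Thresholds (2, 3) are equivalently a factor of 1.5; (2, 4) a
        factor of 2.
        """
        if factor <= 1:
            raise ValueError(f"multiplication factor must exceed 1, got {factor}")
        return cls(t_low=t_low, t_high=t_low * factor, **kwargs)

    @property
    def effective_t_high(self) -> float:
        """``t_high`` with the fourway single-threshold case mapped to +inf."""
        return self.t_high if self.t_high is not None else math.inf

    def key_fields(self) -> tuple:
        """Fields that must agree across the scorecards of one collection."""
        return (self.t_low, self.t_high, self.alpha, self.mode,
                self.significance_policy, self.swap_letter_axes)


def _check_finite(name: str, v: float) -> None:
    if not math.isfinite(v):
        raise ValueError(f"{name} must be finite, got {v} (sanitize inputs upstream)")


def categorize_axis(v: float, t_low: float, t_high: float) -> AxisCategory:
    """Band of a single log2 fold-change.

    Boundary values belong to the outer band: ``|v| = t_low`` is
    MODERATE and ``|v| = t_high`` is EXTREME.
    """
    _check_finite("log2 fold-change", v)
    if not 0 < t_low < t_high:
        raise ValueError(f"need 0 < t_low < t_high, got ({t_low}, {t_high})")
    a = abs(v)
    if a >= t_high:
        return AxisCategory.EXTREME
    if a >= t_low:
        return AxisCategory.MODERATE
    return AxisCategory.CENTRAL


def assign_quadrant(x: float, y: float) -> Quadrant:
    """Quadrant of an (x, y) pair; zero counts as positive."""
    _check_finite("x", x)
    _check_finite("y", y)
    if x >= 0:
        return Quadrant.Q1 if y >= 0 else Quadrant.Q4
    return Quadrant.Q2 if y >= 0 else Quadrant.Q3


def classify_point(x: float, y: float, config: ScorecardConfig) -> RegionAssignment:
    """Classify one gene's fold-change pair under a scorecard config.

    Returns :data:`NOT_REPORTED` for the central/central cell and for
    cells masked by the mode (M/S/R under ``standard``); otherwise the
    quadrant and, except in fourway mode, the region letter.
    """
    _check_finite("x", x)
    _check_finite("y", y)
    t_low, t_high = config.t_low, config.effective_t_high
    cx = categorize_axis(x, t_low, t_high)
    cy = categorize_axis(y, t_low, t_high)
    if cx is AxisCategory.CENTRAL and cy is AxisCategory.CENTRAL:
        return NOT_REPORTED
    quadrant = assign_quadrant(x, y)
    if config.mode == "fourway":
        return RegionAssignment(quadrant, None)
    region = _CATEGORIES_TO_REGION[(cx, cy)]
    if config.swap_letter_axes:
        region = _AXIS_SWAP[region]
    if config.mode == "standard" and region not in STANDARD_REGIONS:
        return NOT_REPORTED
    return RegionAssignment(quadrant, region)


def passes_significance(
    x_p: Optional[float],
    y_p: Optional[float],
    x_category: AxisCategory,
    y_category: AxisCategory,
    config: ScorecardConfig,
) -> bool:
    """Significance filter for a classified gene.

    A missing p-value fails its axis test.  Under the default
    ``non_central_axes`` policy only the axes with a non-central band
    are tested, so genes changing on one axis only (regions D/E/S/R) are
    not discarded for the flat axis' p-value.
    """
    def ok(p: Optional[float]) -> bool:
        return p is not None and not math.isnan(p) and p <= config.alpha

    policy = config.significance_policy
    if policy == "both_axes":
        return ok(x_p) and ok(y_p)
    if policy == "either_axis":
        return ok(x_p) or ok(y_p)
    # non_central_axes
    for p, cat in ((x_p, x_category), (y_p, y_category)):
        if cat is not AxisCategory.CENTRAL and not ok(p):
            return False
    return True


@dataclass(frozen=True)
class ScorecardEntry:
    gene_id: str
    x_fc: float
    y_fc: float
    x_p: Optional[float]
    y_p: Optional[float]
    assignment: RegionAssignment
    annotation: Optional[str] = None


@dataclass
class Scorecard:
    """Classified, significance-filtered gene set for one ordered pair."""

    x_name: str
    y_name: str
    config: ScorecardConfig
    entries: list[ScorecardEntry] = field(default_factory=list)
    dropped: dict[str, int] = field(
        default_factory=lambda: {
            "missing_partner": 0,
            "not_reported": 0,
            "not_significant": 0,
        }
    )

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.x_name, self.y_name)

    def get(self, gene_id: str) -> Optional[ScorecardEntry]:
        return self._index().get(gene_id)

    def _index(self) -> dict[str, ScorecardEntry]:
        idx = getattr(self, "_idx", None)
        if idx is None or len(idx) != len(self.entries):
            idx = {e.gene_id: e for e in self.entries}
            object.__setattr__(self, "_idx", idx)
        return idx

    def __len__(self) -> int:
        return len(self.entries)


def build_scorecard(
    cx: Comparison, cy: Comparison, config: ScorecardConfig
) -> Scorecard:
    """Score genes shared by two comparisons.

    Genes present in only one comparison are dropped and counted under
    ``missing_partner``; the drop counters plus the entry count always
    add up to the size of the union of the two gene sets.
    """
    if cx.name == cy.name:
        raise ValueError("a scorecard needs two distinct comparisons")
    sc = Scorecard(cx.name, cy.name, config)
    common = [g for g in cx.records if g in cy.records]
    only_x = sum(1 for g in cx.records if g not in cy.records)
    only_y = sum(1 for g in cy.records if g not in cx.records)
    sc.dropped["missing_partner"] = only_x + only_y
    if not common:
        warnings.warn(
            f"no genes shared between {cx.name!r} and {cy.name!r}: empty scorecard",
            stacklevel=2,
        )
    t_low, t_high = config.t_low, config.effective_t_high
    for gene in common:
        rx, ry = cx.records[gene], cy.records[gene]
        assignment = classify_point(rx.log2fc, ry.log2fc, config)
        if not assignment.is_reported:
            sc.dropped["not_reported"] += 1
            continue
        cat_x = categorize_axis(rx.log2fc, t_low, t_high)
        cat_y = categorize_axis(ry.log2fc, t_low, t_high)
        if not passes_significance(rx.p_value, ry.p_value, cat_x, cat_y, config):
            sc.dropped["not_significant"] += 1
            continue
        sc.entries.append(
            ScorecardEntry(
                gene_id=gene,
                x_fc=rx.log2fc,
                y_fc=ry.log2fc,
                x_p=rx.p_value,
                y_p=ry.p_value,
                assignment=assignment,
                annotation=rx.annotation if rx.annotation is not None else ry.annotation,
            )
        )
    return sc
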