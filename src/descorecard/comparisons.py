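"""Per-comparison differential-expression tables and pair enumeration.

One *comparison* is a treatment-vs-reference contrast carrying, per
gene, a log2 fold-change and an (upstream-adjusted) p-value.  A study
provides several comparisons, and scorecards are built for every
unordered pair of them; with ``n`` comparisons that is ``n(n-1)/2``
scorecards (15 comparisons give 105, 4 give 6).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "Comparison",
    "ComparisonColumns",
    "ExpressionTable",
    "LoadReport",
    "InputError",
    "read_comparison_table",
    "write_comparison_table",
    "derive_pairwise_comparisons",
    "enumerate_scorecard_pairs",
]

#: log2 fold-changes beyond this magnitude (infinities from zero
#: denominators upstream) are clamped and flagged in the load report.
DEFAULT_FC_CAP = 20.0


class InputError(ValueError):
    """Malformed or contract-violating input data."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene in one comparison."""

    gene_id: str
    log2fc: float
    p_value: Optional[float] = None
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")
        if not math.isfinite(self.log2fc):
            raise InputError(f"log2fc must be finite for {self.gene_id!r}")
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise InputError(
                f"p-value {self.p_value} out of [0, 1] for {self.gene_id!r}"
            )


@dataclass
class Comparison:
    """A named treatment-vs-reference contrast with per-gene records."""

    name: str
    records: dict[str, GeneRecord] = field(default_factory=dict)
    numerator_condition: str = ""
    reference_condition: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("comparison name must be non-empty")
        for gid, rec in self.records.items():
            if gid != rec.gene_id:
                raise InputError(f"record key {gid!r} != gene_id {rec.gene_id!r}")

    def add(self, rec: GeneRecord) -> None:
        if rec.gene_id in self.records:
            raise InputError(f"duplicate gene_id {rec.gene_id!r} in {self.name!r}")
        self.records[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ComparisonColumns:
    """Column roles for one comparison inside a wide results table."""

    name: str
    log2fc: str
    p_value: Optional[str] = None
    annotation: Optional[str] = None


@dataclass
class LoadReport:
    """Accounting of what a table load kept and discarded."""

    path: str = ""
    rows_read: int = 0
    #: per comparison name: {"unparseable_fc": n, "invalid_p": n, "clamped_fc": n}
    dropped: dict[str, dict[str, int]] = field(default_factory=dict)

    def total_dropped(self, name: Optional[str] = None) -> int:
        names = [name] if name is not None else list(self.dropped)
        return sum(
            v
            for n in names
            for k, v in self.dropped.get(n, {}).items()
            if k != "clamped_fc"  # clamped rows are kept, only flagged
        )


def _read_frame(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_comparison_table(
    path: Union[str, Path],
    gene_col: str,
    comparisons: Sequence[ComparisonColumns],
    *,
    log2_transform: bool = False,
    fc_cap: float = DEFAULT_FC_CAP,
) -> tuple[list[Comparison], LoadReport]:
    """Load one or more comparisons from a wide CSV/XLSX results table.

    Parameters
    ----------
    path
        CSV (UTF-8, header row) or XLSX file.
    gene_col
        Name of the gene-identifier column.
    comparisons
        Column roles, one entry per comparison to extract.
    log2_transform
        If the fold-change columns hold raw ratios, take log2 on load.
    fc_cap
        Clamp for non-finite / out-of-range fold-changes; clamped rows
        are kept and counted in the report under ``clamped_fc``.

    Returns
    -------
    (list of Comparison, LoadReport)
        Rows with an unparseable fold-change or an out-of-range p-value
        are dropped per comparison and counted in the report.

    Raises
    ------
    InputError
        Missing declared column, or duplicate gene ids.
    """
    if not comparisons:
        raise InputError("at least one comparison column group is required")
    df = _read_frame(path)
    missing = [
        c
        for c in [gene_col]
        + [cc.log2fc for cc in comparisons]
        + [cc.p_value for cc in comparisons if cc.p_value]
        + [cc.annotation for cc in comparisons if cc.annotation]
        if c not in df.columns
    ]
    if missing:
        raise InputError(f"declared column(s) not in table: {missing}")

    genes = df[gene_col].astype(str)
    dup = genes[genes.duplicated()].unique().tolist()
    if dup:
        raise InputError(f"duplicate gene_id values: {dup}")
    if genes.str.len().eq(0).any():
        raise InputError("empty gene_id encountered")

    report = LoadReport(path=str(path), rows_read=len(df))
    out: list[Comparison] = []
    seen_names: set[str] = set()
    for cc in comparisons:
        if cc.name in seen_names:
            raise InputError(f"duplicate comparison name {cc.name!r}")
        seen_names.add(cc.name)
        drops = {"unparseable_fc": 0, "invalid_p": 0, "clamped_fc": 0}
        fc = pd.to_numeric(df[cc.log2fc], errors="coerce").to_numpy(dtype=float)
        if log2_transform:
            with np.errstate(divide="ignore", invalid="ignore"):
                fc = np.log2(np.where(fc > 0, fc, np.where(np.isnan(fc), np.nan, 0.0)))
        if cc.p_value:
            pv = pd.to_numeric(df[cc.p_value], errors="coerce").to_numpy(dtype=float)
        else:
            pv = np.full(len(df), np.nan)
        notes = (
            df[cc.annotation].astype("string") if cc.annotation else None
        )
        comp = Comparison(name=cc.name)
        for i, gid in enumerate(genes):
            v = fc[i]
            if math.isnan(v):
                drops["unparseable_fc"] += 1
                continue
            if not math.isfinite(v) or abs(v) > fc_cap:
                v = math.copysign(fc_cap, v)
                drops["clamped_fc"] += 1
            p = pv[i]
            if math.isnan(p):
                p = None
            elif not 0 <= p <= 1:
                drops["invalid_p"] += 1
                continue
            note = None
            if notes is not None and pd.notna(notes.iloc[i]):
                note = str(notes.iloc[i])
            comp.add(GeneRecord(gid, float(v), p, note))
        report.dropped[cc.name] = drops
        out.append(comp)
    return out, report


def write_comparison_table(
    comparisons: Sequence[Comparison],
    path: Union[str, Path],
    gene_col: str = "gene",
) -> list[ComparisonColumns]:
    """Write comparisons to one wide CSV; returns the column map to re-read it.

    Genes absent from a comparison get empty cells in its columns, so a
    read-back drops them for that comparison only (round-trip identity
    on records).
    """
    genes: list[str] = []
    seen: set[str] = set()
    for comp in comparisons:
        for g in comp.records:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    data: dict[str, list] = {gene_col: genes}
    colmap: list[ComparisonColumns] = []
    for comp in comparisons:
        fc_col, p_col, a_col = (
            f"{comp.name}__log2fc",
            f"{comp.name}__p",
            f"{comp.name}__annotation",
        )
        colmap.append(ComparisonColumns(comp.name, fc_col, p_col, a_col))
        data[fc_col] = [
            comp.records[g].log2fc if g in comp.records else None for g in genes
        ]
        data[p_col] = [
            comp.records[g].p_value if g in comp.records else None for g in genes
        ]
        data[a_col] = [
            comp.records[g].annotation if g in comp.records else None for g in genes
        ]
    pd.DataFrame(data).to_csv(path, index=False)
    return colmap


@dataclass
class ExpressionTable:
    """Condition x gene expression values (e.g. replicate-averaged FPKM)."""

    values: pd.DataFrame  # index: gene_id, columns: condition labels
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if (vals[np.isfinite(vals)] < 0).any():
            raise InputError("expression values must be non-negative")
        if self.values.columns.duplicated().any() or self.values.index.duplicated().any():
            raise InputError("duplicate condition or gene labels")

    @property
    def conditions(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]


def derive_pairwise_comparisons(
    expr: ExpressionTable, pseudocount: float = 1.0
) -> list[Comparison]:
    """Turn a condition x gene expression table into pairwise comparisons.

    For every unordered condition pair (A, B), in input column order, a
    comparison named ``"A_vs_B"`` holds ``log2((v_A + pc) / (v_B + pc))``
    per gene.  No p-values exist at this point; the significance policy
    decides how missing p-values are treated downstream.  Swapping A and
    B negates every fold-change exactly.
    """
    if pseudocount <= 0:
        raise InputError(f"pseudocount must be positive, got {pseudocount}")
    conds = expr.conditions
    if len(conds) < 2:
        raise InputError("need at least 2 conditions to derive comparisons")
    out: list[Comparison] = []
    for a, b in itertools.combinations(conds, 2):
        comp = Comparison(
            name=f"{a}_vs_{b}", numerator_condition=a, reference_condition=b
        )
        va = expr.values[a]
        vb = expr.values[b]
        for g in expr.genes:
            x, y = va.loc[g], vb.loc[g]
            if pd.isna(x) or pd.isna(y):
                continue  # explicitly missing cell: gene skipped for this pair
            # difference of logs, not log of ratio: exactly antisymmetric
            # under a condition swap
            fc = math.log2(x + pseudocount) - math.log2(y + pseudocount)
            comp.add(GeneRecord(g, fc, None, expr.annotations.get(g)))
        out.append(comp)
    return out


def enumerate_scorecard_pairs(
    comparisons: Sequence[Comparison],
) -> list[tuple[Comparison, Comparison]]:
    """All unordered comparison pairs, each once, in input order.

    The earlier comparison of the input list becomes the x-axis.  The
    number of pairs is the binomial coefficient C(n, 2).
    """
    if len(comparisons) < 2:
        raise InputError("need at least 2 comparisons to enumerate scorecards")
    names = [c.name for c in comparisons]
    if len(set(names)) != len(names):
        raise InputError("comparison names must be unique")
    return list(itertools.combinations(comparisons, 2))
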