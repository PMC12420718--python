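"""Persistence: JSON archives, CSV/XLSX tables, and plain-text logs.

The JSON archive is the lossless store (schema version ``1.0``): an
exported collection re-imports to an equal in-memory object.  Tables
mirror the publication-style outputs — region-count matrix, exclusive
genes, gene occurrences, difference ranking, and a run summary.  The log
is a line-oriented, machine-parseable dump of every reported gene.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from ._version import __version__
from .aggregate import (
    ScorecardCollection,
    exclusive_genes,
    gene_occurrence,
    rank_by_difference,
    region_count_matrix,
)
from .classify import (
    Quadrant,
    Region,
    RegionAssignment,
    Scorecard,
    ScorecardConfig,
    ScorecardEntry,
)

__all__ = [
    "SCHEMA_VERSION",
    "ArchiveError",
    "export_archive",
    "import_archive",
    "write_tables",
    "read_region_counts",
    "write_log",
    "read_log_occurrences",
]

SCHEMA_VERSION = "1.0"

TABLE_NAMES = (
    "region_counts",
    "exclusive_genes",
    "gene_occurrence",
    "difference_ranking",
    "run_summary",
)


class ArchiveError(ValueError):
    """Unreadable, corrupt, or schema-incompatible archive."""


# ---------------------------------------------------------------- archive

def _config_to_dict(cfg: ScorecardConfig) -> dict:
    return {
        "t_low": cfg.t_low,
        "t_high": cfg.t_high,
        "alpha": cfg.alpha,
        "mode": cfg.mode,
        "significance_policy": cfg.significance_policy,
        "region_colors": dict(cfg.region_colors),
        "swap_letter_axes": cfg.swap_letter_axes,
    }


def _config_from_dict(d: dict) -> ScorecardConfig:
    return ScorecardConfig(**d)


def _entry_to_dict(e: ScorecardEntry) -> dict:
    return {
        "gene_id": e.gene_id,
        "x_fc": e.x_fc,
        "y_fc": e.y_fc,
        "x_p": e.x_p,
        "y_p": e.y_p,
        "quadrant": e.assignment.quadrant.value if e.assignment.quadrant else None,
        "region": e.assignment.region.value if e.assignment.region else None,
        "annotation": e.annotation,
    }


def _entry_from_dict(d: dict, where: str) -> ScorecardEntry:
    try:
        assignment = RegionAssignment(
            Quadrant(d["quadrant"]) if d["quadrant"] is not None else None,
            Region(d["region"]) if d["region"] is not None else None,
        )
        return ScorecardEntry(
            gene_id=d["gene_id"],
            x_fc=float(d["x_fc"]),
            y_fc=float(d["y_fc"]),
            x_p=None if d["x_p"] is None else float(d["x_p"]),
            y_p=None if d["y_p"] is None else float(d["y_p"]),
            assignment=assignment,
            annotation=d.get("annotation"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ArchiveError(f"invalid entry in {where}: {exc}") from exc


def export_archive(
    coll: ScorecardCollection,
    path: Union[str, Path],
    *,
    inputs: Sequence[str] = (),
    timestamp: Optional[str] = None,
) -> Path:
    """Serialize a collection to a versioned JSON archive.

    Floats are written with Python's shortest round-trip representation,
    so re-importing restores them bit-exactly.  ``timestamp`` (ISO-8601
    string) is stored only in the provenance block; it defaults to
    absent so that identical runs produce byte-identical archives.
    """
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "study_label": coll.study_label,
        "time_key": coll.time_key,
        "config": _config_to_dict(coll.config) if coll.scorecards else None,
        "scorecards": [
            {
                "x_comparison": sc.x_name,
                "y_comparison": sc.y_name,
                "entries": [_entry_to_dict(e) for e in sc.entries],
                "dropped": dict(sc.dropped),
            }
            for sc in coll
        ],
        "provenance": {
            "software": f"descorecard {__version__}",
            "inputs": list(inputs),
            **({"created": timestamp} if timestamp else {}),
        },
    }
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return path


def import_archive(path: Union[str, Path]) -> ScorecardCollection:
    """Load a JSON archive back into a :class:`ScorecardCollection`.

    Raises :class:`ArchiveError` naming the first invalid element for
    corrupt files, and for any unknown ``schema_version``.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ArchiveError(f"cannot read archive {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ArchiveError("archive root must be a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ArchiveError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    cfg = _config_from_dict(doc["config"]) if doc.get("config") else None
    scorecards = []
    for i, sd in enumerate(doc.get("scorecards", [])):
        where = f"scorecards[{i}]"
        try:
            x, y = sd["x_comparison"], sd["y_comparison"]
        except (KeyError, TypeError) as exc:
            raise ArchiveError(f"invalid {where}: {exc}") from exc
        sc = Scorecard(
            x_name=x,
            y_name=y,
            config=cfg,
            entries=[
                _entry_from_dict(e, f"{where}.entries[{j}]")
                for j, e in enumerate(sd.get("entries", []))
            ],
            dropped=dict(sd.get("dropped", {})),
        )
        scorecards.append(sc)
    time_key = doc.get("time_key")
    return ScorecardCollection(
        scorecards,
        study_label=doc.get("study_label", "study"),
        time_key=dict(time_key) if time_key else None,
    )


# ----------------------------------------------------------------- tables

def _region_counts_frame(coll: ScorecardCollection) -> pd.DataFrame:
    mat = region_count_matrix(coll)
    out = mat.reset_index()
    return out


def _exclusive_frame(coll: ScorecardCollection) -> pd.DataFrame:
    rows = exclusive_genes(coll) if len(coll) >= 2 else []
    return pd.DataFrame(
        [
            {
                "X-axis": x,
                "Y-axis": y,
                "Quadr. ROI": RegionAssignment(q, r).label,
                "Symbol": gid,
            }
            for x, y, q, r, gid in rows
        ],
        columns=["X-axis", "Y-axis", "Quadr. ROI", "Symbol"],
    )


def _occurrence_frame(coll: ScorecardCollection) -> pd.DataFrame:
    occ = gene_occurrence(coll)
    notes = {}
    for sc in coll:
        for e in sc.entries:
            if e.gene_id not in notes and e.annotation:
                notes[e.gene_id] = e.annotation
    rows = sorted(occ.items(), key=lambda kv: (-kv[1].count, kv[0]))
    return pd.DataFrame(
        [
            {"Gene": gid, "Frequency": rec.count, "Notes": notes.get(gid, "")}
            for gid, rec in rows
        ],
        columns=["Gene", "Frequency", "Notes"],
    )


def _difference_frame(coll: ScorecardCollection, top_n: Optional[int]) -> pd.DataFrame:
    rows = rank_by_difference(coll, top_n)
    return pd.DataFrame(
        [
            {
                "Cond. X": r.x_comparison,
                "Cond. Y": r.y_comparison,
                "Quadr.": r.quadrant.value,
                "ROI": r.region.value if r.region else "",
                "Entry": r.gene_id,
                "X fold-change": r.x_fc,
                "Y fold-change": r.y_fc,
                "Difference": r.difference,
            }
            for r in rows
        ],
        columns=[
            "Cond. X", "Cond. Y", "Quadr.", "ROI", "Entry",
            "X fold-change", "Y fold-change", "Difference",
        ],
    )


def _summary_frame(coll: ScorecardCollection) -> pd.DataFrame:
    cfg = coll.config
    # values as strings so CSV and XLSX cells agree byte-for-byte
    rows = [
        {"Item": "study_label", "Value": coll.study_label},
        {"Item": "t_low", "Value": str(cfg.t_low)},
        {"Item": "t_high", "Value": "" if cfg.t_high is None else str(cfg.t_high)},
        {"Item": "alpha", "Value": str(cfg.alpha)},
        {"Item": "mode", "Value": cfg.mode},
        {"Item": "significance_policy", "Value": cfg.significance_policy},
        {"Item": "n_scorecards", "Value": str(len(coll))},
    ]
    for sc in coll:
        label = f"{sc.x_name} | {sc.y_name}"
        rows.append({"Item": f"entries[{label}]", "Value": str(len(sc.entries))})
        for k, v in sorted(sc.dropped.items()):
            rows.append({"Item": f"dropped.{k}[{label}]", "Value": str(v)})
    return pd.DataFrame(rows, columns=["Item", "Value"])


def write_tables(
    coll: ScorecardCollection,
    directory: Union[str, Path],
    formats: Sequence[str] = ("csv",),
    top_n: int = 30,
) -> list[Path]:
    """Write the five study tables as CSV files and/or one XLSX workbook.

    Tables: region counts per scorecard, exclusive genes, gene
    occurrences, top-``top_n`` difference ranking, and a run summary
    (thresholds, alpha, mode, per-scorecard entry and drop counts).
    Row order is deterministic.  Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = {
        "region_counts": _region_counts_frame(coll),
        "exclusive_genes": _exclusive_frame(coll),
        "gene_occurrence": _occurrence_frame(coll),
        "difference_ranking": _difference_frame(coll, top_n),
        "run_summary": _summary_frame(coll),
    }
    # presentation tables round floats (XLSX keeps 15 significant digits,
    # so full doubles would diverge between formats); the JSON archive is
    # the lossless store
    for frame in frames.values():
        for col in frame.columns:
            if frame[col].dtype.kind == "f":
                frame[col] = frame[col].round(9)
    written: list[Path] = []
    for fmt in formats:
        if fmt == "csv":
            for name, frame in frames.items():
                p = directory / f"{name}.csv"
                frame.to_csv(p, index=False)
                written.append(p)
        elif fmt == "xlsx":
            p = directory / "tables.xlsx"
            with pd.ExcelWriter(p, engine="openpyxl") as xl:
                for name, frame in frames.items():
                    frame.to_excel(xl, sheet_name=name, index=False)
            written.append(p)
        else:
            raise ValueError(f"unknown table format {fmt!r} (use csv, xlsx)")
    return written


def read_region_counts(path: Union[str, Path]) -> pd.DataFrame:
    """Read a region-count CSV back into the region_count_matrix shape."""
    df = pd.read_csv(str(path), keep_default_na=False)
    df = df.set_index(["x_comparison", "y_comparison"])
    return df.astype(int)


# -------------------------------------------------------------------- log

_LOG_HEADER = """\
# descorecard log, schema 1.0
# grammar (tab-separated fields):
#   SCORECARD\t<x_comparison>\t<y_comparison>\t<n_entries>
#   CELL\t<quadrant>\t<region|->\t<n_genes>
#   GENE\t<gene_id>\t<x_fc>\t<y_fc>\t<x_p|->\t<y_p|->\t<annotation>
"""


def write_log(coll: ScorecardCollection, path: Union[str, Path]) -> Path:
    """Plain-text dump of every reported gene, grouped by scorecard and cell.

    The line grammar is documented in the file header; occurrence counts
    recovered by parsing the log equal :func:`gene_occurrence`.
    """
    path = Path(path)
    lines = [_LOG_HEADER.rstrip("\n")]
    for sc in coll:
        lines.append(f"SCORECARD\t{sc.x_name}\t{sc.y_name}\t{len(sc.entries)}")
        cells: dict[str, list] = {}
        for e in sc.entries:
            cells.setdefault(e.assignment.label, []).append(e)
        for label in sorted(cells):
            entries = sorted(cells[label], key=lambda e: e.gene_id)
            parts = label.split(" ")
            quadrant = parts[0]
            region = parts[1] if len(parts) > 1 else "-"
            lines.append(f"CELL\t{quadrant}\t{region}\t{len(entries)}")
            for e in entries:
                xp = "-" if e.x_p is None else repr(e.x_p)
                yp = "-" if e.y_p is None else repr(e.y_p)
                note = e.annotation or ""
                lines.append(
                    f"GENE\t{e.gene_id}\t{e.x_fc!r}\t{e.y_fc!r}\t{xp}\t{yp}\t{note}"
                )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_log_occurrences(path: Union[str, Path]) -> dict[str, int]:
    """Parse a log file back to per-gene scorecard-occurrence counts."""
    counts: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("GENE\t"):
            gid = line.split("\t")[1]
            counts[gid] = counts.get(gid, 0) + 1
    return counts
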