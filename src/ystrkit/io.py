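"""Reading and writing haplotype tables and forensic reports.

Haplotype tables are delimited text (CSV or TSV, sniffed from the
extension or delimiter argument) with a header row: a sample-ID column
followed by one column per locus.  DYS385a/b is accepted either as two
columns (``DYS385a``, ``DYS385b``) or as one ``DYS385`` column holding
``"13,17"`` / ``"13-17"``.  Empty or unparseable-by-policy cells become
missing loci, never silent zeros.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .alleles import AlleleCall, MalformedAlleleError
from .haplotypes import DatasetError, Haplotype, PopulationDataset
from .panels import LocusPanel, normalize_locus

if TYPE_CHECKING:  # pragma: no cover
    from .forensic import ForensicReport

__all__ = [
    "read_haplotype_table",
    "write_haplotype_table",
    "write_report",
    "read_report",
    "display_round",
    "TableFormatError",
]

log = logging.getLogger(__name__)

# Sanity bounds on repeat counts; the study observed alleles from 7 to 32.
ALLELE_MIN = 5
ALLELE_MAX = 45

_ID_COLUMNS = {"SAMPLEID", "SAMPLE", "ID", "SAMPLE_ID"}
_AMEL_COLUMNS = {"AMELOGENINYDELETED", "AMELYDELETED", "AMELY"}


class TableFormatError(ValueError):
    """Raised for malformed haplotype or report tables."""


def display_round(x: float, decimals: int = 4) -> str:
    """Format a value for human-readable report tables.

    Truncates toward zero at ``decimals`` places — the convention under
    which 94/95 = 0.98947… prints as ``0.9894`` — so a displayed
    proportion never overstates the underlying value.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    scale = 10**decimals
    return f"{math.trunc(x * scale) / scale:.{decimals}f}"


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def _parse_cell(
    text: str, locus: str, row_label: str, strict_bounds: bool
) -> AlleleCall | None:
    """Parse one allele cell; None means missing."""
    text = text.strip()
    if text in ("", "-", "NA", "na", "null"):
        return None
    try:
        call = AlleleCall.parse(text)
    except MalformedAlleleError as exc:
        raise TableFormatError(f"row {row_label}, column {locus}: {exc}") from None
    if not (ALLELE_MIN <= call.repeats <= ALLELE_MAX):
        msg = (
            f"row {row_label}, column {locus}: allele {call} outside "
            f"sanity bounds [{ALLELE_MIN}, {ALLELE_MAX}]"
        )
        if strict_bounds:
            raise TableFormatError(msg)
        log.warning("%s; treated as missing", msg)
        return None
    return call


def read_haplotype_table(
    path: str | Path,
    panel: LocusPanel,
    *,
    name: str | None = None,
    delimiter: str | None = None,
    strict_bounds: bool = False,
) -> PopulationDataset:
    """Read a haplotype table into a :class:`PopulationDataset`.

    Parameters
    ----------
    path : file path to a CSV/TSV table with a header row.
    panel : locus panel the columns must belong to.
    strict_bounds : if True, alleles outside the 5–45 repeat sanity range
        are an error instead of being logged and treated as missing.
    """
    df = _read_delimited(path, delimiter)
    id_col = None
    locus_cols: dict[str, str] = {}  # column -> canonical locus
    pair_cols: dict[str, list[str]] = {}  # multi-copy locus -> its columns
    amel_col = None
    for col in df.columns:
        squashed = col.strip().upper().replace(" ", "").replace("_", "")
        if squashed in _ID_COLUMNS and id_col is None:
            id_col = col
            continue
        if squashed in _AMEL_COLUMNS:
            amel_col = col
            continue
        locus = normalize_locus(col)
        if locus not in panel.loci:
            raise TableFormatError(
                f"unknown locus column {col!r} (normalised {locus!r}) "
                f"for panel {panel.name}"
            )
        if locus in panel.multi_copy:
            pair_cols.setdefault(locus, []).append(col)
        else:
            if locus in locus_cols:
                raise TableFormatError(f"duplicate column for locus {locus}")
            locus_cols[locus] = col
    if id_col is None:
        id_col = df.columns[0]
        if id_col in locus_cols.values() or any(
            id_col in cols for cols in pair_cols.values()
        ):
            raise TableFormatError("no sample-ID column found")
    for locus, cols in pair_cols.items():
        if len(cols) not in (1, 2):
            raise TableFormatError(f"{locus}: expected 1 or 2 columns, got {len(cols)}")

    haps = []
    for idx, row in df.iterrows():
        sample_id = str(row[id_col]).strip()
        label = f"{idx + 2} (sample {sample_id!r})"  # +2: header + 1-based
        calls: dict = {}
        missing: set[str] = set()
        for locus, col in locus_cols.items():
            call = _parse_cell(str(row[col]), locus, label, strict_bounds)
            if call is None:
                missing.add(locus)
            else:
                calls[locus] = call
        for locus, cols in pair_cols.items():
            if len(cols) == 2:
                cells = [str(row[c]) for c in cols]
            else:
                raw = str(row[cols[0]]).strip()
                cells = [p for p in raw.replace("-", ",").split(",") if p.strip()] or [""]
                if len(cells) == 1 and cells[0]:
                    cells = cells * 2  # homozygous-style single entry
                while len(cells) < 2:
                    cells.append("")
            pair = [_parse_cell(c, locus, label, strict_bounds) for c in cells[:2]]
            if any(p is None for p in pair):
                missing.add(locus)
            else:
                calls[locus] = (pair[0], pair[1])
        amel = False
        if amel_col is not None:
            amel = str(row[amel_col]).strip().lower() in ("1", "true", "yes", "deleted")
        haps.append(
            Haplotype(
                sample_id=sample_id,
                calls=calls,
                amelogenin_y_deleted=amel,
                missing_loci=frozenset(missing),
            )
        )
    try:
        return PopulationDataset(name or Path(path).stem, panel, tuple(haps))
    except DatasetError as exc:
        raise TableFormatError(str(exc)) from None


def write_haplotype_table(
    ds: PopulationDataset, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a dataset as a delimited table (two-column DYS385 dialect)."""
    columns = ["SampleID"]
    for locus in ds.panel.loci:
        if locus in ds.panel.multi_copy:
            columns += [f"{locus}a", f"{locus}b"]
        else:
            columns.append(locus)
    columns.append("AmelY")
    rows = []
    for h in ds.haplotypes:
        row: dict[str, str] = {"SampleID": h.sample_id}
        for locus in ds.panel.loci:
            call = h.calls.get(locus)
            if locus in ds.panel.multi_copy:
                a, b = ("", "") if call is None else (str(call[0]), str(call[1]))
                row[f"{locus}a"], row[f"{locus}b"] = a, b
            else:
                row[locus] = "" if call is None else str(call)
        row["AmelY"] = "deleted" if h.amelogenin_y_deleted else "normal"
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=delimiter, index=False)


def write_report(report: "ForensicReport", path: str | Path, format: str = "json") -> None:
    """Write a forensic report.

    ``json`` round-trips every numeric field at full precision; ``csv``
    is the human-readable per-locus table with values truncated at 4
    decimals (the report's display convention).
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2))
    elif format == "csv":
        rows = []
        for ls in report.per_locus:
            rows.append(
                {
                    "locus": ls.locus,
                    "n_alleles": ls.n_alleles_distinct,
                    "GD": display_round(ls.gene_diversity),
                    "PIC": display_round(ls.pic),
                    "PM": display_round(ls.match_probability),
                    "PD": display_round(ls.power_of_discrimination),
                }
            )
        summary = {
            "locus": "OVERALL",
            "n_alleles": report.total_distinct_alleles,
            "GD": display_round(report.mean_gd),
            "PIC": "",
            "PM": display_round(report.haplotype_match_probability),
            "PD": display_round(report.discrimination_capacity),
        }
        pd.DataFrame(rows + [summary]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> dict:
    """Read back a JSON forensic report as a plain dict."""
    return json.loads(Path(path).read_text())
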