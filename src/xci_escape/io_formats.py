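"""Readers and writers for the tabular and interval formats the pipeline uses.

All tables are tab-separated UTF-8 text with a header row.  Genomic
coordinates are 1-based closed internally (the VCF/GATK convention);
BED input is converted at the boundary.  Missing values are written as
the literal token ``NA``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

#: canonical column names for a variant allelic-count table
VARIANT_COLUMNS = ["line_id", "contig", "position", "ref_count",
                   "alt_count", "total_count", "gene_id"]

#: accepted aliases (GATK ASEReadCounter spelling -> internal)
_VARIANT_ALIASES = {
    "contig": "contig",
    "position": "position",
    "refcount": "ref_count",
    "ref_count": "ref_count",
    "altcount": "alt_count",
    "alt_count": "alt_count",
    "totalcount": "total_count",
    "total_count": "total_count",
    "line_id": "line_id",
    "gene_id": "gene_id",
}

_MANDATORY_VARIANT = ["contig", "position", "ref_count", "alt_count",
                      "total_count"]

ESCAPE_STATUSES = ("escape", "variable", "inactive", "unknown")


class FormatError(ValueError):
    """A file violated the expected tabular format."""


def _to_int(series: pd.Series, colname: str, path) -> pd.Series:
    """Coerce a column to integers, naming the first offending row."""
    coerced = pd.to_numeric(series, errors="coerce")
    bad = coerced.isna() & series.notna()
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"{path}: non-integer value {series[bad].iloc[0]!r} in column "
            f"'{colname}' at row {row}")
    if coerced.isna().any():
        row = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: missing value in column '{colname}' "
                          f"at row {row}")
    if (coerced % 1 != 0).any():
        row = int(np.flatnonzero((coerced % 1 != 0).to_numpy())[0]) + 2
        raise FormatError(f"{path}: non-integer value in column "
                          f"'{colname}' at row {row}")
    return coerced.astype(np.int64)


def read_allelic_counts(path, line_id: str | None = None) -> pd.DataFrame:
    """Read a GATK-ASEReadCounter-style allelic count table.

    Parameters
    ----------
    path
        TSV with at least the columns ``contig``, ``position``,
        ``refCount``, ``altCount``, ``totalCount`` (snake_case accepted).
        A ``line_id`` column makes the file long-format over lines;
        otherwise `line_id` (or the file stem) labels every row.
    line_id
        Line identifier used when the table has no ``line_id`` column.

    Returns
    -------
    DataFrame with columns ``line_id, contig, position, ref_count,
    alt_count, total_count`` (+ ``gene_id`` when present).  Rows with
    ``total_count < 1`` are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _VARIANT_ALIASES:
            rename[col] = _VARIANT_ALIASES[key]
    df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY_VARIANT if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) "
                          f"{', '.join(missing)}")
    # unknown extra columns are ignored
    keep = [c for c in VARIANT_COLUMNS if c in df.columns]
    df = df[keep].copy()
    for col in ("position", "ref_count", "alt_count", "total_count"):
        df[col] = _to_int(df[col], col, path)
    if (df["position"] < 1).any():
        raise FormatError(f"{path}: positions must be >= 1")
    if (df[["ref_count", "alt_count", "total_count"]] < 0).to_numpy().any():
        raise FormatError(f"{path}: negative read counts")
    if "line_id" not in df.columns:
        df.insert(0, "line_id", line_id if line_id is not None else path.stem)
    n_zero = int((df["total_count"] < 1).sum())
    if n_zero:
        logger.info("%s: dropped %d rows with totalCount < 1", path, n_zero)
        df = df[df["total_count"] >= 1]
    if "gene_id" not in df.columns:
        df["gene_id"] = pd.NA
    return df[VARIANT_COLUMNS].reset_index(drop=True)


def read_gene_counts(path) -> pd.DataFrame:
    """Read a gene x line integer count matrix.

    First column is the gene id; remaining columns are line ids.
    Technical replicates (duplicate line columns) are summed.  Duplicate
    gene ids or negative counts raise :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    try:
        # read with explicit names so duplicate line ids (technical
        # replicates) survive pandas' column mangling
        df = pd.read_csv(path, sep="\t", skiprows=1, header=None,
                         names=range(len(header)), index_col=0)
        df.columns = header[1:]
        df.index.name = header[0]
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: ragged or malformed table: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: missing values in count matrix "
                          f"(ragged row?)")
    mat = df.to_numpy()
    if not np.issubdtype(mat.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if (mat < 0).any():
        raise FormatError(f"{path}: negative counts")
    # sum technical replicates sharing a line id
    df = df.T.groupby(level=0, sort=False).sum().T
    df.index.name = "gene_id"
    return df.astype(np.int64)


def read_gene_models(path) -> pd.DataFrame:
    """Read the minimal gene-model table.

    Columns: gene_id, chrom, strand, tss, start, end, is_par,
    human_escape_status.  Enforces ``start <= end`` and that the TSS
    matches the strand (start on '+', end on '-').
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "strand", "tss", "start", "end",
                "is_par", "human_escape_status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id")
    for col in ("tss", "start", "end"):
        df[col] = _to_int(df[col], col, path)
    if (df["start"] > df["end"]).any():
        raise FormatError(f"{path}: start > end")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    plus = df["strand"] == "+"
    if not (df.loc[plus, "tss"] == df.loc[plus, "start"]).all() or \
       not (df.loc[~plus, "tss"] == df.loc[~plus, "end"]).all():
        raise FormatError(f"{path}: tss inconsistent with strand")
    bad = ~df["human_escape_status"].isin(ESCAPE_STATUSES)
    if bad.any():
        raise FormatError(
            f"{path}: unknown escape status "
            f"{df.loc[bad, 'human_escape_status'].iloc[0]!r}")
    df["is_par"] = df["is_par"].astype(bool)
    return df.reset_index(drop=True)


def read_sample_meta(path) -> pd.DataFrame:
    """Read sample metadata (line_id, donor_id, sex)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["line_id", "donor_id", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if df["line_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate line_id")
    if not df["sex"].isin(["male", "female"]).all():
        raise FormatError(f"{path}: sex must be 'male' or 'female'")
    return df.reset_index(drop=True)


def read_intervals(path, known_chroms: Iterable[str] | None = None
                   ) -> pd.DataFrame:
    """Read a BED3+ file into 1-based closed intervals.

    BED is 0-based half-open, so ``(start, end)`` becomes
    ``(start + 1, end)``.  Overlapping intervals are kept unmerged and
    strand is ignored.  Unknown chromosomes are tolerated with a warning
    when `known_chroms` is given.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {i}: fewer than 3 BED "
                                  f"columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer "
                                  f"coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}: line {i}: start >= end")
            name = parts[3] if len(parts) > 3 else f"interval_{i}"
            rows.append((chrom, start + 1, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if known_chroms is not None and len(df):
        unknown = set(df["chrom"]) - set(known_chroms)
        if unknown:
            logger.warning("%s: intervals on unknown chromosome(s): %s",
                           path, ", ".join(sorted(unknown)))
    return df


def write_intervals_bed(intervals: pd.DataFrame, path) -> None:
    """Write 1-based closed intervals back out as BED (0-based half-open)."""
    out = intervals.copy()
    out["start"] = out["start"] - 1
    out[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV: NA tokens, floats to 6 significant digits,
    deterministic column order (as given)."""
    df.to_csv(path, sep="\t", index=index, na_rep=NA_TOKEN,
              float_format="%.6g")


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN],
                       keep_default_na=False, **kwargs)


def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if len(genes) else ""))


def read_gene_list(path) -> list[str]:
    text = Path(path).read_text()
    return [g.strip() for g in text.splitlines() if g.strip()]
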