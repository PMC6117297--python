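"""CSV/TSV contracts for the pipeline's table types.

All interchange files are comma-separated UTF-8 with a header row, "."
decimals and no thousands separators; column matching is case-insensitive.
Malformed rows are rejected with line-numbered diagnostics (header is line
1, so data row ``i`` lives on line ``i + 2``); a missing required column or
an empty file is an error naming the problem.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ("mouse_id", "group", "week", "gfphi_dn3", "dn3")
EVENT_COLUMNS = ("cell_id", "mouse_id", "group", "week", "gfp", "ki67",
                 "dna_content")
MFI_COLUMNS = ("mouse_id", "group", "t0_h", "mfi0", "t1_h", "mfi1")


def _read_table(path: str | Path, required: tuple[str, ...],
                sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def _reject(df: pd.DataFrame, bad: pd.Series, path, reason: str) -> pd.DataFrame:
    if bad.any():
        lines = ", ".join(str(i + 2) for i in df.index[bad][:20])
        logger.warning("%s: rejected %d row(s) (%s) at line(s) %s",
                       path, int(bad.sum()), reason, lines)
    return df.loc[~bad]


def read_count_series(path: str | Path) -> pd.DataFrame:
    """Read a per-mouse count series (mouse_id, group, week, gfphi_dn3, dn3)."""
    df = _read_table(path, COUNT_COLUMNS)
    df = df[list(COUNT_COLUMNS) + [c for c in df.columns
                                   if c not in COUNT_COLUMNS]]
    for col in ("week", "gfphi_dn3", "dn3"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _reject(df, df[["week", "gfphi_dn3", "dn3"]].isna().any(axis=1),
                 path, "non-numeric values")
    df = _reject(df, (df["week"] < 0) | (df["gfphi_dn3"] < 0) | (df["dn3"] < 0),
                 path, "negative values")
    df = _reject(df, df["gfphi_dn3"] > df["dn3"], path, "gfphi_dn3 > dn3")
    if df.empty:
        raise ValueError(f"{path}: no valid rows after filtering")
    return df.reset_index(drop=True)


def write_count_series(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read a per-event flow-style table (one row per measured cell)."""
    df = _read_table(path, EVENT_COLUMNS)
    for col in ("week", "gfp", "ki67", "dna_content"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _reject(df, df[["week", "gfp", "ki67", "dna_content"]].isna().any(axis=1),
                 path, "non-numeric values")
    df = _reject(df, ~(df["gfp"] > 0), path, "non-positive gfp")
    if df.empty:
        raise ValueError(f"{path}: no valid rows after filtering")
    return df.reset_index(drop=True)


def write_event_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_mfi_pairs(path: str | Path) -> pd.DataFrame:
    """Read per-mouse MFI pairs (mouse_id, group, t0_h, mfi0, t1_h, mfi1)."""
    df = _read_table(path, MFI_COLUMNS)
    for col in ("t0_h", "mfi0", "t1_h", "mfi1"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _reject(df, df[["t0_h", "mfi0", "t1_h", "mfi1"]].isna().any(axis=1),
                 path, "non-numeric values")
    if df.empty:
        raise ValueError(f"{path}: no valid rows after filtering")
    return df.reset_index(drop=True)


def read_expression(expr_path: str | Path, annot_path: str | Path,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x samples expression matrix plus gene→chromosome annotation.

    The expression file is TSV or CSV (sniffed from the extension), first
    column gene identifiers, remaining columns one per sample.  Genes absent
    from the annotation are dropped with a logged count at analysis time.
    """
    expr_path = Path(expr_path)
    sep = "\t" if expr_path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        expr = pd.read_csv(expr_path, sep=sep, index_col=0,
                           float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{expr_path}: file is empty") from None
    if expr.empty or expr.shape[1] == 0:
        raise ValueError(f"{expr_path}: no expression data")
    expr.index.name = "gene"
    expr = expr.apply(pd.to_numeric, errors="coerce")
    bad = expr.isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d gene(s) with non-numeric or missing "
                       "values", expr_path, int(bad.sum()))
        expr = expr.loc[~bad]

    annot = _read_table(annot_path, ("gene", "chromosome"))
    return expr, annot


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","
    expr.to_csv(path, sep=sep)
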