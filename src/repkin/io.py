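"""Tab-delimited table, bedGraph and BED readers/writers.

All on-disk formats are plain text.  The TSV dialects are:

- gradient tables: fragment_id, time_min, fraction, signal
- probe tables:    chrom, position, time_min, hh_intensity, hl_intensity
- Z tables:        chrom, position, time_min, z
- timing tables:   fragment_id, trep_min, replication_index
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

GRADIENT_COLUMNS = ["fragment_id", "time_min", "fraction", "signal"]
PROBE_COLUMNS = ["chrom", "position", "time_min", "hh_intensity", "hl_intensity"]
Z_COLUMNS = ["chrom", "position", "time_min", "z"]
TIMING_COLUMNS = ["fragment_id", "trep_min", "replication_index"]

_NUMERIC = {
    "time_min", "fraction", "signal", "position",
    "hh_intensity", "hl_intensity", "z", "trep_min", "replication_index",
}


class TableFormatError(ValueError):
    """Malformed input table; the message carries a 1-based line number."""


def read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a TSV with the given required columns, validating numeric fields.

    Raises :class:`TableFormatError` with the offending line number on
    missing columns or non-numeric values.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise TableFormatError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: line 1: missing required column(s) {', '.join(missing)}"
        )
    for col in columns:
        if col not in _NUMERIC:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise TableFormatError(
                f"{path}: line {line}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        if df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2
            raise TableFormatError(f"{path}: line {line}: missing value in column {col!r}")
        df[col] = coerced
    return df[list(columns)]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_bedgraph(
    path: str | Path,
    chroms: Iterable[str],
    positions: Iterable[int],
    values: Iterable[float],
) -> None:
    """Write point values as 1-bp bedGraph intervals (0-based half-open)."""
    pos = np.asarray(list(positions), dtype=int)
    df = pd.DataFrame(
        {
            "chrom": list(chroms),
            "start": pos,
            "end": pos + 1,
            "value": list(values),
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def write_bed(
    path: str | Path,
    intervals: Iterable[tuple[str, int, int, str, float]],
) -> None:
    """Write (chrom, start, end, name, score) intervals as BED5."""
    rows = list(intervals)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.4g")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TableFormatError(f"{path}: config must be a mapping")
    return cfg
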