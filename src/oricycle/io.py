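"""CSV readers and writers for the pipeline's tabular inputs.

All readers log the file path and row count at INFO level and raise
:class:`~oricycle.errors.ParseError` with the offending path on failure.
Delimiters are sniffed from the extension (``.tsv`` -> tab, else comma).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .qpcr import QPCR_COLUMNS
from .runout import RunoutHistogram, SizeSample

__all__ = [
    "read_histogram",
    "read_sizes",
    "read_qpcr",
    "write_histogram",
    "write_table",
]

log = logging.getLogger("oricycle")


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path} contains no data rows")
    log.info("read %s: %d rows", path, len(df))
    return df


def read_histogram(path: str | Path) -> RunoutHistogram:
    """Read a two-column (bin center fluorescence, count) histogram CSV/TSV."""
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: histogram needs two columns (bin center, count)")
    try:
        return RunoutHistogram(
            bin_centers=df.iloc[:, 0].to_numpy(float),
            counts=df.iloc[:, 1].to_numpy(float),
        )
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_sizes(path: str | Path) -> SizeSample:
    """Read a one-column cell-area (µm²) sample CSV/TSV."""
    df = _read_csv(path)
    try:
        return SizeSample(areas=df.iloc[:, 0].to_numpy(float))
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a long-format qPCR table (sample_id, target, role, cq, efficiency)."""
    df = _read_csv(path)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: qPCR table missing columns {missing}")
    return df


def write_histogram(hist: RunoutHistogram, path: str | Path) -> None:
    df = pd.DataFrame({"fluorescence": hist.bin_centers, "count": hist.counts})
    write_table(df, path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)
    log.info("wrote %s: %d rows", path, len(df))
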