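"""Readers and writers for the pipeline's plain-text tabular formats.

Schemas:
  OTU table     TSV, first column ``sample_id``, remaining columns integer
                genus counts.
  metadata      CSV, first column ``sample_id``, plus ``patient_id``,
                ``site`` and histology columns.
  spectra       CSV, one ``ppm`` column plus one intensity column per
                sample.
  Ct table      CSV with columns ``sample_id``, ``target`` (fn | pan),
                ``ct``.

All readers validate (duplicate ids, negative or fractional counts,
non-monotone ppm axis) and report the offending row/column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .nmr import Spectrum

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_spectra",
    "write_spectra",
    "read_ct",
    "write_ct",
]


class FormatError(ValueError):
    """An input file violates its documented schema."""


def _check_unique_index(idx: pd.Index, what: str) -> None:
    if idx.duplicated().any():
        dup = sorted(set(idx[idx.duplicated()]))
        raise FormatError(f"duplicate sample id(s) {dup} in {what}")


def read_otu_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique_index(df.index, f"OTU table {path}")
    for col in df.columns:
        vals = df[col]
        if (vals < 0).any():
            row = vals.index[vals < 0][0]
            raise FormatError(f"negative count at row {row!r}, column {col!r} in {path}")
        if not np.allclose(vals, vals.astype(np.int64)):
            row = vals.index[(vals != vals.astype(np.int64))][0]
            raise FormatError(f"non-integer count at row {row!r}, column {col!r} in {path}")
    return df.astype(np.int64)


def write_otu_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    _check_unique_index(df.index, f"metadata {path}")
    for col in ("patient_id", "site"):
        if col not in df.columns:
            raise FormatError(f"metadata {path} is missing required column {col!r}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="sample_id")


def read_spectra(path: str | Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    if "ppm" not in df.columns:
        raise FormatError(f"spectra file {path} needs a 'ppm' column")
    sample_cols = [c for c in df.columns if c != "ppm"]
    if not sample_cols:
        raise FormatError(f"spectra file {path} has no sample columns")
    _check_unique_index(pd.Index(sample_cols), f"spectra {path}")
    ppm = df["ppm"].to_numpy(dtype=float)
    d = np.diff(ppm)
    if not ((d > 0).all() or (d < 0).all()):
        bad = int(np.flatnonzero(~((d > 0) if d[0] > 0 else (d < 0)))[0]) + 2
        raise FormatError(f"non-monotone ppm axis in {path} near line {bad}")
    return [Spectrum(ppm=ppm, intensity=df[c].to_numpy(dtype=float), sample_id=c)
            for c in sample_cols]


def write_spectra(df: pd.DataFrame, path: str | Path) -> None:
    """Write a spectra frame (ppm column + one column per sample)."""
    df.to_csv(path, index=False)


def read_ct(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"sample_id", "target", "ct"}
    if not need <= set(df.columns):
        raise FormatError(f"Ct table {path} must have columns {sorted(need)}")
    dup = df.duplicated(subset=["sample_id", "target"])
    if dup.any():
        first = df.loc[dup, "sample_id"].iloc[0]
        raise FormatError(f"duplicate Ct record for sample {first!r} in {path}")
    return df


def write_ct(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
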