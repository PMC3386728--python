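"""Strict CSV round-tripping for feature tables.

Feature CSVs carry one header line with columns
``fruit_id, class, sniff_index, ch01..ch32, FI, AFI`` (channel count may
vary; acoustic columns are optional for an e-nose-only table).  Decimal
points are always '.', independent of locale.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

META_COLUMNS = ("fruit_id", "class", "sniff_index")
_CHANNEL_RE = re.compile(r"^ch\d{2,}$")


def channel_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if _CHANNEL_RE.match(c)]


def feature_columns(df: pd.DataFrame) -> list[str]:
    cols = channel_columns(df)
    for c in ("FI", "AFI"):
        if c in df.columns:
            cols.append(c)
    return cols


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature table.

    Raises on a missing ``class`` column, absence of any feature column,
    non-numeric feature cells, or duplicate (fruit_id, sniff_index) keys.
    """
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing required column 'class'")
    feats = feature_columns(df)
    if not feats:
        raise ValueError(f"{path}: no feature columns (chNN / FI / AFI) found")
    bad = [c for c in feats + ["class"]
           if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ValueError(f"{path}: non-numeric values in column(s) {bad}")
    if {"fruit_id", "sniff_index"} <= set(df.columns):
        dup = df.duplicated(subset=["fruit_id", "sniff_index"])
        if dup.any():
            keys = df.loc[dup, ["fruit_id", "sniff_index"]].head(3).to_dict("records")
            raise ValueError(f"{path}: duplicate (fruit_id, sniff_index) keys, e.g. {keys}")
    return df


def write_feature_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table; floats keep full round-trip precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path):
    """Read a raw sniff-trace CSV (columns ``time_s, ch01..ch32``) as a SniffTrace."""
    from aromafuse.synthetic import SniffTrace

    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    chans = channel_columns(df)
    if not chans:
        raise ValueError(f"{path}: no channel columns found")
    return SniffTrace(
        time=df["time_s"].to_numpy(float),
        resistance=df[chans].to_numpy(float),
    )


def write_trace_csv(trace, path: str | Path) -> None:
    df = pd.DataFrame(
        trace.resistance,
        columns=[f"ch{k:02d}" for k in range(1, trace.resistance.shape[1] + 1)],
    )
    df.insert(0, "time_s", trace.time)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
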