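"""File I/O: TSV channel tables, HDF5 signal containers, connectome CSVs
and JSON run reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .connectome import CHANNEL_TABLE_COLUMNS, Connectome, connectome_to_frame

__all__ = [
    "read_channel_table",
    "write_channel_table",
    "write_signals_h5",
    "read_signals_h5",
    "write_connectome_csv",
    "read_connectome_csv",
    "write_report_json",
]


class ChannelTableError(ValueError):
    """Validation failure in a channel table, naming the offending line."""


def read_channel_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV channel table.

    Required columns (any order): subject_id, channel_id, x_mm, y_mm, z_mm,
    roi_id, roi_name, hemisphere.  Coordinates must be finite numbers,
    hemisphere must be L or R, and (subject_id, channel_id) must be unique.
    Errors name the first offending data line (1-based, header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CHANNEL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ChannelTableError(
            f"{path}: missing column(s) {sorted(missing)}")
    for col in ("x_mm", "y_mm", "z_mm"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() | ~np.isfinite(num)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ChannelTableError(
                f"{path}: non-numeric or non-finite {col} at line {line}")
        df[col] = num
    roi = pd.to_numeric(df["roi_id"], errors="coerce")
    if roi.isna().any():
        line = int(roi.isna().idxmax()) + 2
        raise ChannelTableError(f"{path}: non-integer roi_id at line {line}")
    df["roi_id"] = roi.astype(int)
    bad_hemi = ~df["hemisphere"].isin(["L", "R"])
    if bad_hemi.any():
        line = int(bad_hemi.idxmax()) + 2
        raise ChannelTableError(
            f"{path}: hemisphere must be L or R at line {line}")
    dup = df.duplicated(subset=["subject_id", "channel_id"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ChannelTableError(
            f"{path}: duplicate (subject_id, channel_id) at line {line}")
    return df[list(CHANNEL_TABLE_COLUMNS)]


def write_channel_table(channels: pd.DataFrame, path: str | Path) -> None:
    channels.to_csv(path, sep="\t", index=False)


def write_signals_h5(
    path: str | Path,
    signals: Mapping[str, np.ndarray],
    channel_ids: Mapping[str, list[str]],
    fs: float,
) -> None:
    """One dataset per subject (channels x samples) with sampling-rate and
    channel-id attributes."""
    with h5py.File(path, "w") as f:
        for subj in sorted(signals):
            d = f.create_dataset(subj, data=np.asarray(signals[subj]))
            d.attrs["sampling_rate_hz"] = float(fs)
            d.attrs["channel_ids"] = [str(c) for c in channel_ids[subj]]


def read_signals_h5(
    path: str | Path,
) -> tuple[dict[str, np.ndarray], dict[str, list[str]], float]:
    """Inverse of :func:`write_signals_h5`; checks a single sampling rate."""
    signals: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    rates = set()
    with h5py.File(path, "r") as f:
        for subj in f:
            d = f[subj]
            signals[subj] = d[()]
            ids[subj] = [c.decode() if isinstance(c, bytes) else str(c)
                         for c in d.attrs["channel_ids"]]
            rates.add(float(d.attrs["sampling_rate_hz"]))
    if len(rates) != 1:
        raise ValueError(f"{path}: inconsistent sampling rates {rates}")
    return signals, ids, rates.pop()


def write_connectome_csv(c: Connectome, path: str | Path) -> None:
    connectome_to_frame(c).to_csv(path, index=False)


def read_connectome_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2,
                                     sort_keys=True))
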