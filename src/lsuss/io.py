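"""File formats: delimited-text series, change-point lists, score tables,
TOML run configs and a versioned binary array container.

Everything round-trips: write followed by read reproduces the object
(bitwise for the binary container).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import ChangePointSet, TimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_changepoints",
    "write_changepoints",
    "write_scores",
    "read_config_toml",
    "write_config_toml",
]


def read_timeseries(path, fmt: str = "auto", header: bool = False,
                    delimiter: str = ",") -> TimeSeries:
    """Read a series from delimited text (one row per step, one column per
    channel) or the ``.npy`` binary container.

    ``fmt`` is ``"csv"``, ``"npy"`` or ``"auto"`` (by extension).  With
    ``header=True`` the first row is consumed as channel names.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "npy" if path.suffix == ".npy" else "csv"
    if fmt == "npy":
        return TimeSeries(np.load(path, allow_pickle=False))
    try:
        df = pd.read_csv(path, header=0 if header else None,
                         delimiter=delimiter)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: ragged rows ({e})") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for r, row in enumerate(arr):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at line "
                        f"{r + (2 if header else 1)}") from None
        arr = arr.astype(np.float64)
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + (2 if header else 1)
        raise ValueError(f"{path}: ragged or missing value near line {line}")
    names = [str(c) for c in df.columns] if header else None
    return TimeSeries(arr.astype(np.float64), channel_names=names)


def write_timeseries(ts: TimeSeries, path, fmt: str = "auto") -> None:
    path = Path(path)
    if fmt == "auto":
        fmt = "npy" if path.suffix == ".npy" else "csv"
    if fmt == "npy":
        np.save(path, ts.values)
        return
    df = pd.DataFrame(ts.values, columns=ts.channel_names)
    df.to_csv(path, index=False, header=ts.channel_names is not None)


def read_changepoints(path, n_ref: int | None = None) -> ChangePointSet:
    """One non-negative integer index per line; must be strictly increasing.
    An empty file is a valid empty set."""
    path = Path(path)
    indices: list[int] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        s = raw.strip()
        if not s:
            continue
        try:
            v = int(s)
        except ValueError:
            raise ValueError(f"{path}:{ln}: not an integer: {s!r}") from None
        if v < 0:
            raise ValueError(f"{path}:{ln}: negative index {v}")
        indices.append(v)
    arr = np.asarray(indices, dtype=np.int64)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValueError(f"{path}: indices must be strictly increasing")
    if n_ref is None:
        n_ref = int(arr[-1]) + 1 if arr.size else 1
    return ChangePointSet(indices=arr, n_ref=n_ref)


def write_changepoints(cps: ChangePointSet, path) -> None:
    Path(path).write_text("".join(f"{int(i)}\n" for i in cps.indices))


def write_scores(df: pd.DataFrame, path) -> None:
    """Score table as CSV with a documented header (one row per recording
    plus the ``mean`` row)."""
    df.to_csv(path, index_label="recording")


# --- flat TOML config ------------------------------------------------------

def read_config_toml(path) -> dict:
    import tomllib
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if v is None:
        return '""'
    return json.dumps(str(v))


def write_config_toml(cfg: dict, path) -> None:
    """Serialize a flat configuration dict as TOML (provenance dump)."""
    lines = [f"{k} = {_toml_value(v)}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")
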