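"""Core time-series and subsequence data model.

Conventions used throughout the package:

* arrays are ``(n, NC)`` — one row per time step, one column per channel;
* indices are 0-based and ranges half-open; a change-point at index ``t``
  means the first sample of the new regime is at ``t``;
* subsequence ``j`` of length ``m`` is the window ``values[j : j+m, :]``;
  a series of length ``n`` has ``n - m + 1`` such windows (stride 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TimeSeries",
    "SubsequenceSet",
    "ChangePointSet",
    "extract_all_subsequences",
    "znormalize_window",
]

#: standard deviations below this are treated as zero (degenerate channel)
DEGENERATE_STD = 1e-12


@dataclass(frozen=True)
class TimeSeries:
    """A finite multichannel time series.

    Parameters
    ----------
    values
        ``(n, NC)`` array of real samples.  A 1-D array is promoted to a
        single-channel column.
    sample_rate
        Samples per second; metadata only, never used in computation.
    channel_names
        Optional list of ``NC`` channel labels.
    """

    values: np.ndarray
    sample_rate: float | None = None
    channel_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise ValueError(f"values must be 1-D or 2-D, got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"need n >= 1 and NC >= 1, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values; "
                             "missing data is not supported")
        object.__setattr__(self, "values", v)
        if self.channel_names is not None and len(self.channel_names) != v.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {v.shape[1]} channels")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SubsequenceSet:
    """All length-``m`` windows of a series, stride 1 (a zero-copy view)."""

    source: TimeSeries
    m: int

    def __post_init__(self) -> None:
        if not (2 <= self.m <= self.source.n):
            raise ValueError(
                f"subsequence length m={self.m} out of range [2, n={self.source.n}]")

    @property
    def count(self) -> int:
        return self.source.n - self.m + 1

    @property
    def windows(self) -> np.ndarray:
        """``(count, m, NC)`` view; ``windows[j] == source.values[j:j+m, :]``."""
        # sliding_window_view yields (count, NC, m); put time back in the middle
        return sliding_window_view(self.source.values, self.m, axis=0).transpose(0, 2, 1)


@dataclass(frozen=True)
class ChangePointSet:
    """Strictly increasing change-point indices into a series of length n_ref."""

    indices: np.ndarray
    n_ref: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64).ravel()
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise ValueError("change-point indices must be strictly increasing")
        if idx.size and (idx[0] < 0 or idx[-1] >= self.n_ref):
            raise ValueError(
                f"change-point indices must lie in [0, {self.n_ref})")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


def extract_all_subsequences(ts: TimeSeries, m: int) -> SubsequenceSet:
    """Return the all-subsequence set of ``ts``: every length-``m`` window,
    stride 1, channel order preserved.

    Raises
    ------
    ValueError
        if ``m`` is outside ``[2, ts.n]``.
    """
    if not (2 <= m <= ts.n):
        raise ValueError(f"subsequence length m={m} out of range [2, n={ts.n}]")
    return SubsequenceSet(ts, m)


def znormalize_window(w: np.ndarray, epsilon: float = DEGENERATE_STD) -> np.ndarray:
    """Z-normalize a single ``(m, NC)`` window channel-by-channel.

    Each channel is shifted to mean 0 and scaled to (population, ddof=0)
    standard deviation 1.  A channel whose standard deviation is below
    ``epsilon`` is returned as all zeros, which keeps downstream distances
    finite for constant segments.
    """
    w = np.asarray(w, dtype=np.float64)
    if w.ndim == 1:
        w = w[:, None]
    if w.shape[0] < 2:
        raise ValueError("window must have m >= 2 rows")
    mu = w.mean(axis=0)
    sd = w.std(axis=0)
    out = np.zeros_like(w)
    ok = sd >= epsilon
    out[:, ok] = (w[:, ok] - mu[ok]) / sd[ok]
    return out


def znormalize_windows(windows: np.ndarray, epsilon: float = DEGENERATE_STD) -> np.ndarray:
    """Vectorized :func:`znormalize_window` over a ``(count, m, NC)`` stack."""
    windows = np.asarray(windows, dtype=np.float64)
    mu = windows.mean(axis=1, keepdims=True)
    sd = windows.std(axis=1, keepdims=True)
    safe = np.where(sd >= epsilon, sd, 1.0)
    out = (windows - mu) / safe
    out = np.where(sd >= epsilon, out, 0.0)
    return out
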