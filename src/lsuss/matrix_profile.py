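"""Classic (raw-subsequence) matrix profile.

The matrix profile of a series records, for every subsequence, the distance
to and index of its nearest non-trivial neighbour under the z-normalized
Euclidean distance.  Arcs drawn from each subsequence to its neighbour are
the raw material of the semantic-segmentation curves in :mod:`lsuss.arc_curve`.

Supports:

* bidirectional or forward-only (streaming-friendly) neighbour search;
* a temporal constraint ``tc`` limiting how far in time an arc may point,
  needed whenever the same regime type recurs in disjoint segments;
* a trivial-match exclusion zone around each subsequence's own position.

Distances between multichannel windows are per-channel z-normalized and then
combined as the Euclidean norm over the concatenated channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len, irfft, rfft
from scipy.spatial.distance import cdist

from .signal import DEGENERATE_STD, SubsequenceSet, TimeSeries, znormalize_windows

__all__ = [
    "MatrixProfile",
    "default_exclusion",
    "distance_profile",
    "apply_exclusion",
    "stamp",
    "fluss_multichannel_cac",
]

#: sentinel for "no admissible neighbour"
NO_PARTNER = -1


def default_exclusion(m: int) -> int:
    """Trivial-match exclusion radius: ``ceil(m/4)``, the convention of
    standard matrix-profile implementations."""
    return math.ceil(m / 4)


@dataclass(frozen=True)
class MatrixProfile:
    """Nearest-neighbour profile ``(p, i)`` over subsequences or latent rows.

    ``p[j]`` is the distance from item ``j`` to its nearest admissible
    neighbour ``i[j]``; ``p[j] = inf`` and ``i[j] = -1`` when no admissible
    neighbour exists.  ``tc is None`` means unconstrained.
    """

    p: np.ndarray
    i: np.ndarray
    m: int | None
    tc: int | None
    direction: str  # "bidirectional" | "forward"
    excl: int

    def __post_init__(self) -> None:
        if self.direction not in ("bidirectional", "forward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if len(self.p) != len(self.i):
            raise ValueError("p and i must have equal length")

    def __len__(self) -> int:
        return len(self.p)


def _znormed_flat(A: SubsequenceSet) -> np.ndarray:
    """Per-channel z-normalized windows flattened to ``(count, m*NC)``."""
    return znormalize_windows(A.windows).reshape(A.count, -1)


def distance_profile(A: SubsequenceSet, query_idx: int,
                     method: str = "direct") -> np.ndarray:
    """Distance profile of window ``query_idx``: its z-normalized Euclidean
    distance to every window of ``A`` (no masking applied).

    ``method="direct"`` z-normalizes every window and takes pairwise norms;
    ``method="fft"`` uses the classic FFT sliding-dot-product similarity
    search per channel.  The two agree to ~1e-6 absolute.
    """
    if not (0 <= query_idx < A.count):
        raise ValueError(f"query_idx {query_idx} out of range [0, {A.count})")
    if method == "direct":
        Z = _znormed_flat(A)
        return cdist(Z[query_idx:query_idx + 1], Z)[0]
    if method == "fft":
        x = A.source.values
        q = A.windows[query_idx]
        sq = np.zeros(A.count)
        for c in range(x.shape[1]):
            d = _mass_channel(x[:, c], q[:, c])
            sq += d * d
        return np.sqrt(sq)
    raise ValueError(f"unknown method {method!r}")


def _mass_channel(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """FFT-based z-normalized Euclidean distance profile for one channel.

    Degenerate (constant) windows follow the zero-vector convention of
    :func:`lsuss.signal.znormalize_window`: constant-vs-constant distance is
    0, constant-vs-normal is ``sqrt(m)``.
    """
    n, m = len(t), len(q)
    L = n - m + 1
    # sliding dot products via FFT correlation
    size = next_fast_len(n + m)
    Ft = rfft(t, size)
    Fq = rfft(q[::-1], size)
    qt = irfft(Ft * Fq, size)[m - 1:m - 1 + L]
    # rolling moments of the series windows
    csum = np.concatenate(([0.0], np.cumsum(t)))
    csum2 = np.concatenate(([0.0], np.cumsum(t * t)))
    mu = (csum[m:] - csum[:-m]) / m
    var = (csum2[m:] - csum2[:-m]) / m - mu * mu
    sd = np.sqrt(np.maximum(var, 0.0))
    mq, sq = q.mean(), q.std()
    q_deg = sq < DEGENERATE_STD
    t_deg = sd < DEGENERATE_STD
    if q_deg:
        return np.where(t_deg, 0.0, np.sqrt(m))
    corr = (qt - m * mq * mu) / (m * sq * np.where(t_deg, 1.0, sd))
    d2 = 2.0 * m * (1.0 - corr)
    d = np.sqrt(np.maximum(d2, 0.0))
    return np.where(t_deg, np.sqrt(m), d)


def apply_exclusion(d: np.ndarray, center: int, excl: int) -> np.ndarray:
    """Return a copy of ``d`` with entries within ``excl`` of ``center``
    (inclusive) set to infinity."""
    if excl < 0:
        raise ValueError("excl must be >= 0")
    out = np.array(d, dtype=np.float64, copy=True)
    lo = max(0, center - excl)
    hi = min(len(out), center + excl + 1)
    out[lo:hi] = np.inf
    return out


def _masked_min(D: np.ndarray, q0: int, lo: int, tc: int | None,
                direction: str, excl: int) -> tuple[np.ndarray, np.ndarray]:
    """Min/argmin of a block of distance rows after admissibility masking.

    ``D[r, c]`` is the distance from item ``q0 + r`` to item ``lo + c``.
    Ties break to the smallest admissible index (argmin's first occurrence).
    """
    nr, ncol = D.shape
    delta = (np.arange(lo, lo + ncol)[None, :] - np.arange(q0, q0 + nr)[:, None])
    mask = np.abs(delta) <= excl
    if tc is not None:
        mask |= np.abs(delta) > tc
    if direction == "forward":
        mask |= delta <= 0
    D = np.where(mask, np.inf, D)
    idx = np.argmin(D, axis=1)
    p = D[np.arange(nr), idx]
    i = lo + idx
    i[~np.isfinite(p)] = NO_PARTNER
    return p, i


def stamp(ts: TimeSeries, m: int, tc: int | None = None,
          direction: str = "bidirectional", excl: int | None = None,
          chunk: int = 256) -> MatrixProfile:
    """Compute the matrix profile of ``ts`` with subsequence length ``m``.

    Every subsequence is matched against all admissible partners — outside
    the exclusion zone, inside the temporal constraint (when finite), and
    strictly later in time when ``direction="forward"``.  Queries are
    processed in chunks so memory stays bounded by ``chunk`` distance rows.
    """
    from .signal import extract_all_subsequences

    A = extract_all_subsequences(ts, m)
    if excl is None:
        excl = default_exclusion(m)
    if tc is not None and tc <= excl:
        raise ValueError(
            f"temporal constraint tc={tc} must exceed exclusion radius excl={excl}")
    Z = _znormed_flat(A)
    cnt = A.count
    p = np.full(cnt, np.inf)
    i = np.full(cnt, NO_PARTNER, dtype=np.int64)
    for q0 in range(0, cnt, chunk):
        q1 = min(cnt, q0 + chunk)
        if tc is None:
            lo, hi = 0, cnt
        elif direction == "forward":
            lo, hi = q0, min(cnt, q1 + tc)
        else:
            lo, hi = max(0, q0 - tc), min(cnt, q1 + tc)
        D = cdist(Z[q0:q1], Z[lo:hi])
        p[q0:q1], i[q0:q1] = _masked_min(D, q0, lo, tc, direction, excl)
    return MatrixProfile(p=p, i=i, m=m, tc=tc, direction=direction, excl=excl)


def fluss_multichannel_cac(ts: TimeSeries, m: int, tc: int | None = None,
                           direction: str = "bidirectional",
                           excl: int | None = None,
                           iac_trials: int = 1000, iac_seed: int = 0):
    """Channel-averaged segmentation curve: the multichannel baseline that
    computes a single-channel matrix profile and corrected arc curve per
    channel and returns their elementwise mean.

    Returns a :class:`lsuss.arc_curve.CorrectedArcCurve`.
    """
    from .arc_curve import CorrectedArcCurve, cac_from_profile

    cacs = []
    for c in range(ts.n_channels):
        chan = TimeSeries(ts.values[:, c])
        mp = stamp(chan, m, tc=tc, direction=direction, excl=excl)
        cacs.append(cac_from_profile(mp, n_trials=iac_trials, seed=iac_seed).cac)
    return CorrectedArcCurve(cac=np.mean(cacs, axis=0))
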