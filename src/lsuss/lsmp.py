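"""Latent Space Matrix Profile (LSMP).

Nearest-neighbour profile over latent vectors (autoencoder encodings of the
subsequences), using plain — not z-normalized — Euclidean distance: the
latent rows are feature vectors, not raw windows, so shift/scale invariance
is neither needed nor meaningful.  A finite temporal constraint ``tc`` is
mandatory: it makes repeated regime types segmentable and bounds the work
per row to a ``2*tc + 1`` band of the distance matrix.

Three computation modes:

* :func:`lsmp_full` — the whole profile in one pass (queries chunked so no
  more than a small block of the banded distance matrix is live at once);
* :func:`batched_collapse` — consecutive ``t_lim``-row chunks, each collapsed
  to a partial profile and merged by elementwise minimum over the overlap;
  bounds memory for arbitrarily long series and is the basis of
  epsilon-real-time operation (accumulate epsilon rows, then append);
* :class:`LsmpState` / :func:`online_append` — incremental streaming update.
  With forward-only arcs nothing behind the stream head ever needs
  recomputation; bidirectionally the trailing ``2*tc - 1`` positions are
  re-derived at each append because they may point into the new data.

This module also houses the latent-feature distance baseline
(:func:`lfmd_changepoints`): adjacent-window latent distances whose local
maxima are taken as change-points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .autoencoder import LatentSet, TrainedAutoencoder
from .matrix_profile import NO_PARTNER, MatrixProfile
from .signal import ChangePointSet, TimeSeries

__all__ = [
    "LsmpState",
    "latent_distance_profile",
    "lsmp_full",
    "batched_collapse",
    "online_append",
    "lfmd_changepoints",
]

#: peak number of simultaneously materialized distance entries in the most
#: recent banded computation (instrumentation for the memory contract)
last_peak_distance_entries: int = 0


def _rows(F) -> np.ndarray:
    if isinstance(F, LatentSet):
        return F.F
    return np.asarray(F, dtype=np.float64)


def latent_distance_profile(F, query_idx: int, tc: int, excl: int = 0) -> np.ndarray:
    """Euclidean distances from latent row ``query_idx`` to all rows inside
    the temporal-constraint band, exclusion-masked; entries outside the band
    carry the infinity sentinel.  Length equals the number of rows."""
    X = _rows(F)
    n = len(X)
    if not (0 <= query_idx < n):
        raise ValueError(f"query_idx {query_idx} out of range [0, {n})")
    if tc <= excl:
        raise ValueError(f"tc={tc} must exceed excl={excl}")
    out = np.full(n, np.inf)
    lo, hi = max(0, query_idx - tc), min(n, query_idx + tc + 1)
    out[lo:hi] = np.linalg.norm(X[lo:hi] - X[query_idx], axis=1)
    out[max(0, query_idx - excl):query_idx + excl + 1] = np.inf
    return out


def _banded_partial(X: np.ndarray, start: int, stop: int, tc: int,
                    direction: str, excl: int, offset: int = 0,
                    chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Profile of rows ``[start, stop)`` of ``X`` with partners restricted to
    ``X`` itself (band-masked).  ``offset`` is the global index of ``X[0]``;
    returned indices are global.  Ties break to the smallest partner index.
    """
    global last_peak_distance_entries
    n = len(X)
    m = stop - start
    p = np.full(m, np.inf)
    i = np.full(m, NO_PARTNER, dtype=np.int64)
    for q0 in range(start, stop, chunk):
        q1 = min(stop, q0 + chunk)
        if direction == "forward":
            lo, hi = q0, min(n, q1 + tc)
        else:
            lo, hi = max(0, q0 - tc), min(n, q1 + tc)
        if hi <= lo:
            continue
        D = cdist(X[q0:q1], X[lo:hi])
        last_peak_distance_entries = max(last_peak_distance_entries, D.size)
        delta = np.arange(lo, hi)[None, :] - np.arange(q0, q1)[:, None]
        mask = (np.abs(delta) <= excl) | (np.abs(delta) > tc)
        if direction == "forward":
            mask |= delta <= 0
        D = np.where(mask, np.inf, D)
        idx = np.argmin(D, axis=1)
        pv = D[np.arange(len(D)), idx]
        iv = lo + idx + offset
        iv[~np.isfinite(pv)] = NO_PARTNER
        p[q0 - start:q1 - start] = pv
        i[q0 - start:q1 - start] = iv
    return p, i


def lsmp_full(F, tc: int, direction: str = "bidirectional",
              excl: int = 0) -> MatrixProfile:
    """Latent space matrix profile over all rows of ``F``.

    ``tc`` is required and finite; ``excl`` masks trivial matches between
    encodings of heavily overlapping windows (adjacent windows share
    ``m - 1`` samples and stay near-duplicates after encoding).
    """
    X = _rows(F)
    if tc <= excl:
        raise ValueError(f"tc={tc} must exceed excl={excl}")
    p, i = _banded_partial(X, 0, len(X), tc, direction, excl)
    m = F.m if isinstance(F, LatentSet) else None
    return MatrixProfile(p=p, i=i, m=m, tc=tc, direction=direction, excl=excl)


def _merge_min(p: np.ndarray, i: np.ndarray, p_new: np.ndarray,
               i_new: np.ndarray, at: int) -> None:
    """Elementwise-minimum merge of a partial profile into ``(p, i)`` at
    offset ``at``; on ties the smaller partner index wins."""
    sl = slice(at, at + len(p_new))
    po, io = p[sl], i[sl]
    better = (p_new < po) | ((p_new == po) & (i_new != NO_PARTNER) &
                             ((io == NO_PARTNER) | (i_new < io)))
    p[sl] = np.where(better, p_new, po)
    i[sl] = np.where(better, i_new, io)


def batched_collapse(F, t_lim: int, tc: int, direction: str = "bidirectional",
                     excl: int = 0) -> MatrixProfile:
    """Compute the LSMP chunk-by-chunk with bounded memory.

    The first batch covers rows ``[0, t_lim)``.  Every further batch starts
    ``2*tc - 1`` rows (bidirectional) or ``tc`` rows (forward) before the
    previous batch end, so positions whose band straddles a batch boundary
    are re-derived and merged by elementwise minimum.  The result equals
    :func:`lsmp_full` on the full latent set.
    """
    X = _rows(F)
    if t_lim <= 2 * tc:
        raise ValueError(f"t_lim={t_lim} must exceed 2*tc={2 * tc}")
    if tc <= excl:
        raise ValueError(f"tc={tc} must exceed excl={excl}")
    n = len(X)
    p = np.full(n, np.inf)
    i = np.full(n, NO_PARTNER, dtype=np.int64)
    overlap = 2 * tc - 1 if direction == "bidirectional" else tc
    # chunk queries so a live distance block (chunk x (chunk + 2 tc)) never
    # exceeds the t_lim x (2 tc + 1) memory contract
    chunk = max(1, int(np.sqrt(tc * tc + t_lim * (2 * tc + 1)) - tc))
    end = min(n, t_lim)
    pv, iv = _banded_partial(X[:end], 0, end, tc, direction, excl, chunk=chunk)
    p[:end], i[:end] = pv, iv
    while end < n:
        a = end - overlap
        end = min(n, end + t_lim)
        Xw = X[a:end]
        pv, iv = _banded_partial(Xw, 0, len(Xw), tc, direction, excl,
                                 offset=a, chunk=chunk)
        _merge_min(p, i, pv, iv, a)
    m = F.m if isinstance(F, LatentSet) else None
    return MatrixProfile(p=p, i=i, m=m, tc=tc, direction=direction, excl=excl)


# ---------------------------------------------------------------------------
# streaming

@dataclass(frozen=True)
class LsmpState:
    """Running state of a streamed LSMP.

    ``buffer`` holds the most recent latent rows needed by the next append:
    ``tc`` rows with forward arcs, ``3*tc - 1`` rows bidirectionally (the
    trailing ``2*tc - 1`` re-derived positions reach back a further ``tc``
    rows for their partners).  ``epsilon_batch`` is the number of new rows
    accumulated before each append — the epsilon of epsilon-real-time.
    """

    p: np.ndarray
    i: np.ndarray
    tc: int
    direction: str
    excl: int
    buffer: np.ndarray
    buffer_start: int       # global index of buffer[0]
    epsilon_batch: int = 1

    @property
    def count(self) -> int:
        return len(self.p)

    @classmethod
    def initialize(cls, rows, tc: int, direction: str = "forward",
                   excl: int = 0, epsilon_batch: int | None = None) -> "LsmpState":
        """Start a stream from at least one latent row."""
        X = _rows(rows)
        if len(X) < 1:
            raise ValueError("need at least one initial row")
        if tc <= excl:
            raise ValueError(f"tc={tc} must exceed excl={excl}")
        if epsilon_batch is None:
            epsilon_batch = 1
        p, i = _banded_partial(X, 0, len(X), tc, direction, excl)
        keep = tc if direction == "forward" else 3 * tc - 1
        buf = X[max(0, len(X) - keep):].copy()
        return cls(p=p, i=i, tc=tc, direction=direction, excl=excl,
                   buffer=buf, buffer_start=len(X) - len(buf),
                   epsilon_batch=epsilon_batch)

    def as_profile(self) -> MatrixProfile:
        return MatrixProfile(p=self.p.copy(), i=self.i.copy(), m=None,
                             tc=self.tc, direction=self.direction, excl=self.excl)


def online_append(state: LsmpState, new_rows) -> LsmpState:
    """Extend a streamed LSMP with new latent rows.

    Forward mode: existing entries within ``tc`` of the stream head can only
    improve (their profile value never increases); nothing is recomputed.
    Bidirectional mode: the trailing ``2*tc - 1`` entries are re-derived
    because they may now point into the new rows.  After any sequence of
    appends the state equals the offline profile of the concatenation.
    """
    new = _rows(new_rows)
    if new.size and new.ndim != 2:
        raise ValueError("new rows must be a 2-D array")
    if len(new) == 0:
        return state
    if new.shape[1] != state.buffer.shape[1]:
        raise ValueError(
            f"latent dim {new.shape[1]} does not match stream dim "
            f"{state.buffer.shape[1]}")
    tc, excl, direction = state.tc, state.excl, state.direction
    s = state.count
    X = np.concatenate([state.buffer, new], axis=0)  # global rows from buffer_start
    off = state.buffer_start
    if direction == "forward":
        # recompute (improve-only) every position whose forward band reaches
        # into the new rows: positions >= s - tc, all present in the buffer
        r0 = max(0, s - tc)
    else:
        r0 = max(0, s - (2 * tc - 1))
    pv, iv = _banded_partial(X, r0 - off, len(X), tc, direction, excl, offset=off)
    p = np.concatenate([state.p, np.full(len(new), np.inf)])
    i = np.concatenate([state.i, np.full(len(new), NO_PARTNER, dtype=np.int64)])
    if direction == "forward":
        _merge_min(p, i, pv, iv, r0)
    else:
        p[r0:], i[r0:] = pv, iv
    keep = tc if direction == "forward" else 3 * tc - 1
    total = s + len(new)
    buf_start = max(0, total - keep)
    buf = X[buf_start - off:]
    return replace(state, p=p, i=i, buffer=buf.copy(), buffer_start=buf_start)


# ---------------------------------------------------------------------------
# latent-feature distance baseline

def lfmd_changepoints(ts: TimeSeries, m: int, overlap: int,
                      model: TrainedAutoencoder,
                      excl_windows: int | None = None) -> ChangePointSet:
    """Adjacent-window latent distance baseline.

    Consecutive windows (step ``m - overlap``) are encoded; the Euclidean
    distance between each adjacent pair of latent vectors forms a distance
    curve whose strict local maxima above its global mean — thinned with an
    exclusion radius of one window — are reported as change-points at the
    window boundaries.
    """
    step = m - overlap
    if step <= 0:
        raise ValueError(f"overlap={overlap} must be smaller than m={m}")
    if not (0 <= overlap):
        raise ValueError("overlap must be >= 0")
    starts = np.arange(0, ts.n - m + 1, step)
    if len(starts) < 3:
        return ChangePointSet(indices=np.array([], dtype=np.int64), n_ref=ts.n)
    windows = np.stack([ts.values[s0:s0 + m] for s0 in starts])
    Z = model.encode(windows)
    d = np.linalg.norm(np.diff(Z, axis=0), axis=1)  # length = n_windows - 1
    mean = d.mean()
    # strict local maxima above the mean
    cand = [q for q in range(1, len(d) - 1)
            if d[q] > d[q - 1] and d[q] > d[q + 1] and d[q] > mean]
    if excl_windows is None:
        excl_windows = max(1, int(np.ceil(m / step)))
    cand.sort(key=lambda q: -d[q])
    kept: list[int] = []
    for q in cand:
        if all(abs(q - r) > excl_windows for r in kept):
            kept.append(q)
    idx = np.sort([int(starts[q + 1]) for q in kept]).astype(np.int64)
    return ChangePointSet(indices=idx, n_ref=ts.n)
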