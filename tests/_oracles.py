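"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from definitions (per-pair loops,
explicit window statistics) rather than reusing any code path from the
package, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def znorm_loop(w: np.ndarray) -> np.ndarray:
    """Z-normalize one (m, NC) window per channel, the long way."""
    out = np.zeros_like(w, dtype=float)
    for c in range(w.shape[1]):
        col = w[:, c]
        sd = col.std()
        if sd >= 1e-12:
            out[:, c] = (col - col.mean()) / sd
    return out


def brute_distance(values: np.ndarray, m: int, j: int, k: int) -> float:
    """Z-normalized Euclidean distance between windows j and k of a series."""
    zj = znorm_loop(values[j:j + m])
    zk = znorm_loop(values[k:k + m])
    return float(np.sqrt(((zj - zk) ** 2).sum()))


def brute_stamp(values: np.ndarray, m: int, tc, direction: str,
                excl: int) -> tuple[np.ndarray, np.ndarray]:
    """O(n^2 m) matrix profile from the definition, smallest-index ties."""
    n = len(values)
    cnt = n - m + 1
    Z = np.stack([znorm_loop(values[j:j + m]).ravel() for j in range(cnt)])
    p = np.full(cnt, np.inf)
    i = np.full(cnt, -1, dtype=np.int64)
    for j in range(cnt):
        d = np.sqrt(((Z - Z[j]) ** 2).sum(axis=1))
        for k in range(cnt):
            if abs(k - j) <= excl:
                continue
            if tc is not None and abs(k - j) > tc:
                continue
            if direction == "forward" and k <= j:
                continue
            if d[k] < p[j]:
                p[j], i[j] = d[k], k
    return p, i


def brute_lsmp(F: np.ndarray, tc: int, direction: str,
               excl: int) -> tuple[np.ndarray, np.ndarray]:
    """Banded latent matrix profile by exhaustive pairwise search."""
    n = len(F)
    p = np.full(n, np.inf)
    i = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        for k in range(n):
            if abs(k - j) <= excl or abs(k - j) > tc:
                continue
            if direction == "forward" and k <= j:
                continue
            d = float(np.linalg.norm(F[j] - F[k]))
            if d < p[j]:
                p[j], i[j] = d, k
    return p, i


def brute_count_arcs(i: np.ndarray) -> np.ndarray:
    """Per-position crossing counts by iterating every arc and position."""
    L = len(i)
    ac = np.zeros(L)
    for j, b in enumerate(i):
        if b == -1:
            continue
        lo, hi = min(j, b), max(j, b)
        for k in range(lo + 1, hi):
            ac[k] += 1
    return ac


def rolling_stats_loop(v: np.ndarray, w: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position truncated rolling mean/std by explicit slicing."""
    L = len(v)
    mu = np.empty(L)
    sd = np.empty(L)
    for j in range(L):
        if mode == "centered":
            seg = v[max(0, j - w):min(L, j + w + 1)]
        else:
            seg = v[max(0, j - 2 * w):j + 1]
        mu[j] = seg.mean()
        sd[j] = seg.std()
    return mu, sd
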