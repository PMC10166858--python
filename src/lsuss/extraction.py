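"""Change-point extraction from a corrected arc curve.

Three extractors, in increasing order of autonomy:

* :func:`rea` — the k globally lowest valleys (requires knowing the number
  of change-points); an exclusion zone around each accepted valley prevents
  the k picks collapsing into one dip.
* :func:`lrea` — the same selection applied to a locally z-scored CAC
  (rolling mean/std), so locally sharp valleys win over globally low
  plateaus; converges to :func:`rea` as the rolling window saturates.
* :func:`ltea` — count-free and online-capable: the locally scaled CAC is
  thresholded (default -1, i.e. one standard deviation below the local
  mean), each maximal sub-threshold run ("valley") contributes its minimum,
  and nearby shallower valleys are dropped by the same exclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .arc_curve import CorrectedArcCurve
from .signal import ChangePointSet

__all__ = ["ScaledCac", "rea", "scale_cac", "lrea", "ltea",
           "default_local_window"]

_SIGMA_FLOOR = 1e-12


def _cac_values(cac) -> np.ndarray:
    if isinstance(cac, CorrectedArcCurve):
        return np.asarray(cac.cac, dtype=np.float64)
    return np.asarray(cac, dtype=np.float64)


@dataclass(frozen=True)
class ScaledCac:
    """A CAC standardized by rolling statistics (Eq.-style local z-score)."""

    values: np.ndarray
    mu_rolling: np.ndarray
    sigma_rolling: np.ndarray


def default_local_window(gt: ChangePointSet) -> int:
    """Rolling half-width for the local extractors: the mean gap between
    known (training-set) change-points, including the edge segments."""
    if len(gt) == 0:
        raise ValueError("need at least one change-point to estimate a gap")
    edges = np.concatenate(([0], gt.indices, [gt.n_ref]))
    return int(round(np.mean(np.diff(edges))))


def rea(cac, k: int, excl_width: int) -> ChangePointSet:
    """Regime extraction: iteratively take the global minimum of the curve,
    mask ``excl_width`` positions either side, repeat ``k`` times.

    Returns the accepted positions in sorted order.  If fewer than ``k``
    admissible minima exist a warning is issued and the ones found are
    returned.
    """
    v = _cac_values(cac)
    if k < 1:
        raise ValueError("k must be >= 1")
    if v.size == 0:
        raise ValueError("empty curve")
    work = v.copy()
    found: list[int] = []
    for _ in range(k):
        j = int(np.argmin(work))
        if not np.isfinite(work[j]):
            warnings.warn(
                f"only {len(found)} of {k} requested change-points are "
                "admissible under the exclusion rule", stacklevel=2)
            break
        found.append(j)
        work[max(0, j - excl_width):j + excl_width + 1] = np.inf
    return ChangePointSet(indices=np.sort(found).astype(np.int64), n_ref=len(v))


def scale_cac(cac, local_window: int, scaling_mode: str = "centered") -> ScaledCac:
    """Standardize a curve by rolling mean and (population) std.

    ``centered`` uses the window ``[j - w, j + w]`` truncated at the
    boundaries; ``trailing`` uses the past-only window ``[j - 2w, j]`` (the
    online variant — no future values are touched).  Positions whose rolling
    std is (numerically) zero map to 0.
    """
    v = _cac_values(cac)
    if local_window < 2:
        raise ValueError("local_window must be >= 2")
    if scaling_mode not in ("centered", "trailing"):
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")
    L = len(v)
    # center before the cumulative sums: the rolling variance is
    # shift-invariant and this avoids catastrophic cancellation on flat
    # curves; v[0] keeps the shift causal (trailing mode sees no future)
    g = float(v[0])
    v0 = v - g
    c1 = np.concatenate(([0.0], np.cumsum(v0)))
    c2 = np.concatenate(([0.0], np.cumsum(v0 * v0)))
    j = np.arange(L)
    if scaling_mode == "centered":
        lo = np.maximum(0, j - local_window)
        hi = np.minimum(L - 1, j + local_window)
    else:
        lo = np.maximum(0, j - 2 * local_window)
        hi = j
    cnt = (hi - lo + 1).astype(np.float64)
    mu0 = (c1[hi + 1] - c1[lo]) / cnt
    var = (c2[hi + 1] - c2[lo]) / cnt - mu0 * mu0
    sigma = np.sqrt(np.maximum(var, 0.0))
    mu = mu0 + g
    out = np.zeros(L)
    ok = sigma >= _SIGMA_FLOOR
    out[ok] = (v[ok] - mu[ok]) / sigma[ok]
    return ScaledCac(values=out, mu_rolling=mu, sigma_rolling=sigma)


def lrea(cac, k: int, local_window: int, excl_width: int) -> ChangePointSet:
    """Local regime extraction: :func:`rea` on the locally z-scored curve."""
    scaled = scale_cac(cac, local_window, "centered")
    return rea(scaled.values, k, excl_width)


def ltea(cac, local_window: int, threshold: float = -1.0,
         excl_width: int = 0, scaling_mode: str = "centered") -> ChangePointSet:
    """Local threshold extraction: count-free change-point detection.

    The locally scaled curve is clipped — every value above ``threshold``
    becomes 1 — and each maximal run of un-clipped values is a candidate
    valley contributing its argmin (ties to the smallest index).  Valleys
    are then accepted deepest-first; a valley whose minimum lies within
    ``excl_width`` of an already accepted deeper minimum is dropped.  An
    empty result is valid (no structure below threshold).
    """
    if threshold >= 1:
        raise ValueError("threshold must be < 1 (the clip value)")
    scaled = scale_cac(cac, local_window, scaling_mode).values
    clipped = np.where(scaled > threshold, 1.0, scaled)
    L = len(clipped)
    in_valley = clipped != 1.0
    minima: list[tuple[float, int]] = []
    j = 0
    while j < L:
        if in_valley[j]:
            j1 = j
            while j1 < L and in_valley[j1]:
                j1 += 1
            seg = clipped[j:j1]
            arg = j + int(np.argmin(seg))
            minima.append((clipped[arg], arg))
            j = j1
        else:
            j += 1
    minima.sort(key=lambda t: (t[0], t[1]))  # deepest first, ties by index
    kept: list[int] = []
    for _, pos in minima:
        if all(abs(pos - r) > excl_width for r in kept):
            kept.append(pos)
    return ChangePointSet(indices=np.sort(kept).astype(np.int64), n_ref=L)
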