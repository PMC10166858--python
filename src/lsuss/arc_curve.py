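"""Arc curves: from a matrix-profile index vector to a change-point likelihood.

Each subsequence's arc links it to its nearest neighbour.  Counting, for
every position, how many arcs cross strictly over it yields the Arc Curve
(AC).  Homogeneous regions accumulate many crossings; transitions between
regimes accumulate few.  Normalizing the AC by the Idealized Arc Curve (IAC)
— the expected AC when every arc points to a random admissible partner —
corrects the inevitable decay of crossings towards the series edges and maps
the curve into [0, 1].  The result is the Corrected Arc Curve (CAC), whose
low values mark likely change-points.

The bidirectional unconstrained IAC has the closed form
``iac[k] = 2 k (L-1-k) / (L-1)`` (an inverted parabola of height (L-1)/2).
Directional or temporally constrained nulls have no closed form here and are
estimated by Monte-Carlo simulation with a fixed seed, then cached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_profile import NO_PARTNER, MatrixProfile

__all__ = [
    "ArcCurve",
    "IdealizedArcCurve",
    "CorrectedArcCurve",
    "count_arcs",
    "idealized_arc_curve",
    "corrected_arc_curve",
    "cac_from_profile",
]


@dataclass(frozen=True)
class ArcCurve:
    """Per-position count of arcs crossing strictly over that position."""

    ac: np.ndarray


@dataclass(frozen=True)
class IdealizedArcCurve:
    """Expected arc curve of a structureless series (unclamped values).

    ``mode`` records whether the values come from the analytic parabola or
    from Monte-Carlo simulation over the admissible partner set.
    """

    iac: np.ndarray
    mode: str  # "bidirectional_analytic" | "simulated"
    direction: str
    tc: int | None
    n_trials: int
    seed: int


@dataclass(frozen=True)
class CorrectedArcCurve:
    """Change-point likelihood curve; values in [0, 1], low = likely change."""

    cac: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cac, dtype=np.float64)
        object.__setattr__(self, "cac", c)

    def __len__(self) -> int:
        return len(self.cac)


def count_arcs(i: np.ndarray) -> ArcCurve:
    """Count, for every position, the arcs crossing strictly over it.

    Entry ``j`` with partner ``b = i[j]`` contributes +1 to every position
    strictly between ``min(j, b)`` and ``max(j, b)``; endpoints do not
    count.  Entries equal to the no-partner sentinel (-1) are skipped.
    Runs in O(L + arcs) with a difference-array sweep.
    """
    i = np.asarray(i, dtype=np.int64)
    L = len(i)
    src = np.arange(L)
    ok = (i != NO_PARTNER) & (i != src)  # zero-span arcs cross nothing
    if np.any((i[ok] < 0) | (i[ok] >= L)):
        raise ValueError("index vector contains out-of-range entries")
    a = np.minimum(src[ok], i[ok])
    b = np.maximum(src[ok], i[ok])
    # +1 just right of the left endpoint, -1 at the right endpoint
    start = np.bincount(a + 1, minlength=L + 1)[:L]
    stop = np.bincount(b, minlength=L + 1)[:L]
    ac = np.cumsum(start - stop).astype(np.float64)
    return ArcCurve(ac=ac)


def _simulate_iac(L: int, direction: str, tc: int | None,
                  n_trials: int, seed: int) -> np.ndarray:
    """Monte-Carlo IAC: average arc counts of random admissible index vectors.

    For each position the partner is drawn uniformly from the admissible set
    of the same direction / temporal constraint (self excluded).  Positions
    with an empty admissible set contribute no arc.
    """
    rng = np.random.default_rng(seed)
    j = np.arange(L)
    span = tc if tc is not None else L  # effective radius
    if direction == "forward":
        n_right = np.minimum(L - 1 - j, span)
        n_left = np.zeros(L, dtype=np.int64)
    else:
        n_left = np.minimum(j, span)
        n_right = np.minimum(L - 1 - j, span)
    total = n_left + n_right
    drawable = total > 0
    acc = np.zeros(L + 1)
    jd = j[drawable]
    left_d = n_left[drawable]
    tot_d = total[drawable]
    lo_d = jd - left_d
    for _ in range(n_trials):
        u = rng.integers(0, tot_d)
        # map the flat draw onto [j-left, j-1] then [j+1, j+right]
        k = np.where(u < left_d, lo_d + u, jd + 1 + (u - left_d))
        a = np.minimum(jd, k)
        b = np.maximum(jd, k)
        acc[:L] += np.bincount(a + 1, minlength=L + 1)[:L]
        acc[:L] -= np.bincount(b, minlength=L + 1)[:L]
    return np.cumsum(acc[:L]) / n_trials


_IAC_CACHE: dict[tuple, np.ndarray] = {}


def idealized_arc_curve(L: int, direction: str = "bidirectional",
                        tc: int | None = None, n_trials: int = 1000,
                        seed: int = 0) -> IdealizedArcCurve:
    """Idealized (null-model) arc curve for a series of ``L`` positions.

    Bidirectional and unconstrained: the analytic inverted parabola.  Any
    other combination is simulated with ``n_trials`` random index vectors
    (deterministic given ``seed``) and cached by configuration.
    """
    if L < 3:
        raise ValueError(f"need L >= 3 positions, got {L}")
    if direction == "bidirectional" and tc is None:
        k = np.arange(L, dtype=np.float64)
        iac = 2.0 * k * (L - 1 - k) / (L - 1)
        return IdealizedArcCurve(iac=iac, mode="bidirectional_analytic",
                                 direction=direction, tc=tc,
                                 n_trials=0, seed=seed)
    key = (L, direction, tc, n_trials, seed)
    if key not in _IAC_CACHE:
        _IAC_CACHE[key] = _simulate_iac(L, direction, tc, n_trials, seed)
    return IdealizedArcCurve(iac=_IAC_CACHE[key], mode="simulated",
                             direction=direction, tc=tc,
                             n_trials=n_trials, seed=seed)


def corrected_arc_curve(ac: ArcCurve, iac: IdealizedArcCurve) -> CorrectedArcCurve:
    """``cac = min(ac / max(iac, 1), 1)``.

    The IAC is clamped to >= 1 before division so edge positions cannot blow
    up; positions whose unclamped IAC is below 1 carry essentially no
    information and are reported as 1 ("no change-point evidence").
    """
    if len(ac.ac) != len(iac.iac):
        raise ValueError(
            f"length mismatch: ac has {len(ac.ac)}, iac has {len(iac.iac)}")
    denom = np.maximum(iac.iac, 1.0)
    cac = np.minimum(ac.ac / denom, 1.0)
    cac = np.where(iac.iac < 1.0, 1.0, cac)
    return CorrectedArcCurve(cac=cac)


def cac_from_profile(mp: MatrixProfile, n_trials: int = 1000,
                     seed: int = 0) -> CorrectedArcCurve:
    """Corrected arc curve of a matrix profile: count the arcs of ``mp.i``
    and normalize by the idealized curve matching ``mp.direction``/``mp.tc``."""
    ac = count_arcs(mp.i)
    iac = idealized_arc_curve(len(mp), direction=mp.direction, tc=mp.tc,
                              n_trials=n_trials, seed=seed)
    return corrected_arc_curve(ac, iac)
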