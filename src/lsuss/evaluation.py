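"""Segmentation scoring against ground-truth change-points.

The core quantity is ScoreRegimes: each ground-truth change-point is paired
with its nearest predicted point and the summed absolute index error is
normalized by ``N_GT * n`` — a length-free score in [0, 1] for any sane
prediction.  For count-free (online) extractors the number of predictions
may differ from the truth, so the Prediction Loss MAE additionally weights
the mean absolute error by the deviation of the prediction ratio
``N_pred / N_GT`` from 1.

The combination rule for Prediction Loss MAE is a pinned, documented config
enum: ``inflation_default`` computes ``(1 + |1 - ratio|) * MAE`` (a perfect
count leaves the MAE untouched, count errors inflate it);
``as_printed_abs`` computes ``|1 - ratio| * MAE`` (zero whenever the count
is right, kept for comparability with that convention).  Results carry the
interpretation used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import ChangePointSet

__all__ = [
    "SegmentationScore",
    "match_and_mae",
    "score_regimes",
    "prediction_loss_mae",
    "score_recording",
    "score_dataset",
]

PREDICTION_LOSS_MODES = ("inflation_default", "as_printed_abs")


@dataclass(frozen=True)
class SegmentationScore:
    """Per-recording segmentation metrics."""

    score_regimes: float
    mae: float
    n_pred: int
    n_gt: int
    prediction_ratio: float
    prediction_loss_mae: float
    n: int
    loss_mode: str = "inflation_default"


def _indices(cps) -> np.ndarray:
    if isinstance(cps, ChangePointSet):
        return np.asarray(cps.indices, dtype=np.int64)
    return np.asarray(cps, dtype=np.int64)


def match_and_mae(pred, gt, n: int) -> tuple[list[tuple[int, int]], float]:
    """Pair every ground-truth point with its nearest predicted point.

    Ties go to the earlier predicted index; predicted points may be reused.
    Returns the ``(gt, pred)`` pairs and the mean absolute index distance
    over ground-truth points.  With no predictions at all the MAE is ``n``
    (maximal penalty) and a warning is issued.
    """
    g = _indices(gt)
    p = _indices(pred)
    if g.size == 0:
        raise ValueError("ground truth must be non-empty")
    if p.size == 0:
        warnings.warn("no predicted change-points; MAE set to series length",
                      stacklevel=2)
        return [], float(n)
    pairs = []
    errs = np.empty(len(g))
    for idx, t in enumerate(g):
        d = np.abs(p - t)
        b = int(np.argmin(d))  # first occurrence = earlier index on ties
        pairs.append((int(t), int(p[b])))
        errs[idx] = d[b]
    return pairs, float(errs.mean())


def score_regimes(pred, gt, n: int) -> float:
    """Summed matched absolute error over ``N_GT * n`` — equivalently the
    matched MAE divided by the series length."""
    if n <= 0:
        raise ValueError("series length n must be positive")
    _, mae = match_and_mae(pred, gt, n)
    return mae / n


def prediction_loss_mae(pred, gt, n: int,
                        mode: str = "inflation_default") -> float:
    """MAE weighted by the prediction-count ratio (see module docstring)."""
    if mode not in PREDICTION_LOSS_MODES:
        raise ValueError(f"mode must be one of {PREDICTION_LOSS_MODES}")
    g = _indices(gt)
    p = _indices(pred)
    if g.size == 0:
        raise ValueError("ground truth must be non-empty")
    _, mae = match_and_mae(pred, gt, n)
    dev = abs(1.0 - len(p) / len(g))
    if mode == "as_printed_abs":
        return dev * mae
    return (1.0 + dev) * mae


def score_recording(pred, gt, n: int,
                    loss_mode: str = "inflation_default") -> SegmentationScore:
    """All metrics for one recording."""
    g = _indices(gt)
    p = _indices(pred)
    _, mae = match_and_mae(pred, gt, n)
    return SegmentationScore(
        score_regimes=mae / n,
        mae=mae,
        n_pred=len(p),
        n_gt=len(g),
        prediction_ratio=len(p) / len(g),
        prediction_loss_mae=prediction_loss_mae(pred, gt, n, loss_mode),
        n=n,
        loss_mode=loss_mode,
    )


def score_dataset(results: list[SegmentationScore]) -> pd.DataFrame:
    """Per-recording scores plus an unweighted ``mean`` row.

    Returns a DataFrame with one row per recording (index 0..R-1) and a
    final row labelled ``"mean"`` averaging the numeric columns.
    """
    if not results:
        raise ValueError("need at least one recording")
    df = pd.DataFrame([vars(r) for r in results])
    num = df[["score_regimes", "mae", "prediction_ratio", "prediction_loss_mae"]]
    mean_row = num.mean()
    summary = df.copy()
    summary.loc["mean", mean_row.index] = mean_row
    return summary
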