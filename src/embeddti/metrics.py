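"""Regression metrics for binding-affinity prediction.

Mean squared error, concordance index (CI), and Pearson / Spearman
correlations. The CI is the fraction of correctly ordered prediction pairs
among all pairs with distinct true affinities; a tie in the predictions
contributes 0.5 through the step function h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PairedScores",
    "mse",
    "step_h",
    "concordance_index",
    "pearson",
    "spearman",
]


@dataclass
class PairedScores:
    """Equal-length vectors of true labels and model predictions."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=np.float64)
        self.y_pred = np.asarray(self.y_pred, dtype=np.float64)
        if self.y_true.shape != self.y_pred.shape or self.y_true.ndim != 1:
            raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
        if not (np.isfinite(self.y_true).all() and np.isfinite(self.y_pred).all()):
            raise ValueError("scores must be finite")


def _as_arrays(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    pair = PairedScores(np.asarray(y_true, dtype=np.float64),
                        np.asarray(y_pred, dtype=np.float64))
    return pair.y_true, pair.y_pred


def mse(y_true, y_pred) -> float:
    """Mean squared error, (1/N) sum (y_i - p_i)^2."""
    yt, yp = _as_arrays(y_true, y_pred)
    if yt.size == 0:
        raise ValueError("mse of empty vectors is undefined")
    return float(np.mean((yt - yp) ** 2))


def step_h(x: float) -> float:
    """Step function: 0 for x < 0, 0.5 for x == 0, 1 for x > 0."""
    if x < 0:
        return 0.0
    if x == 0:
        return 0.5
    return 1.0


def concordance_index(y_true, y_pred) -> float:
    """Concordance index over all ordered pairs with distinct true values.

    CI = (1/Z) * sum_{delta_x > delta_y} h(b_x - b_y), where Z is the number
    of pairs with strictly different true affinities; pairs tied in the true
    value are excluded from both the sum and Z.
    """
    yt, yp = _as_arrays(y_true, y_pred)
    order = np.argsort(yt, kind="stable")
    yt_s, yp_s = yt[order], yp[order]
    total = 0.0
    z = 0
    # for each j, count pairs (i, j) with yt_i > yt_j using the sorted order
    for j in range(len(yt_s)):
        for i in range(j + 1, len(yt_s)):
            if yt_s[i] > yt_s[j]:
                z += 1
                total += step_h(yp_s[i] - yp_s[j])
    if z == 0:
        raise ValueError("concordance index undefined: all true values are equal")
    return total / z


def pearson(y_true, y_pred) -> float:
    """Pearson correlation: cov(X, Y) / (sigma_X * sigma_Y)."""
    yt, yp = _as_arrays(y_true, y_pred)
    if yt.size < 2:
        raise ValueError("pearson requires at least 2 points")
    sx = yt.std()
    sy = yp.std()
    if sx == 0 or sy == 0:
        raise ValueError("pearson undefined for a constant vector")
    return float(np.mean((yt - yt.mean()) * (yp - yp.mean())) / (sx * sy))


def spearman(y_true, y_pred) -> float:
    """Spearman rank correlation.

    Without ties this equals 1 - 6*sum(d_i^2) / (n(n^2-1)) on the rank
    vectors; with ties, average ranks are used and the Pearson correlation
    of the rank vectors is returned (the two coincide in the tie-free case).
    """
    yt, yp = _as_arrays(y_true, y_pred)
    if yt.size < 2:
        raise ValueError("spearman requires at least 2 points")
    return pearson(rankdata(yt), rankdata(yp))
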