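"""Train/test partitioning and the prediction-accuracy metric suite.

Errors are defined as predicted − observed throughout (so a positive bias
means over-prediction), MAPE is in percent, and PMSE is the root mean
squared error, reported alongside MSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegenerateError, LengthMismatchError
from .variables import DataTable


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy summary for one prediction/observation pairing.

    r / r_squared are the Pearson correlation of predicted vs observed and
    its square; mse is in (kcal/kg)², mad / bias / pmse in kcal/kg, mape
    in percent.
    """

    r: float
    r_squared: float
    mse: float
    mad: float
    mape: float
    bias: float
    pmse: float
    n: int

    def __post_init__(self) -> None:
        assert self.mse >= 0 and self.mad >= 0
        assert abs(self.pmse - math.sqrt(self.mse)) <= 1e-9 * max(1.0, self.pmse)

    def as_dict(self) -> dict[str, float]:
        return {
            "r": self.r, "r_squared": self.r_squared, "mse": self.mse,
            "mad": self.mad, "mape": self.mape, "bias": self.bias,
            "pmse": self.pmse, "n": self.n,
        }

    def __str__(self) -> str:
        return (
            f"n={self.n}  r={self.r:.4f}  R2={self.r_squared:.4f}  "
            f"MSE={self.mse:.2f}  MAD={self.mad:.2f}  MAPE={self.mape:.2f}%  "
            f"bias={self.bias:.2f}  PMSE={self.pmse:.2f}"
        )


def per_sample_bias(predicted: float, observed: float) -> float:
    """Single-sample bias: predicted − observed."""
    return predicted - observed


def compute_metrics(
    predicted: Sequence[float], observed: Sequence[float]
) -> MetricsReport:
    """r, R², MSE, MAD, MAPE, bias and PMSE of a prediction vector.

    Raises LengthMismatchError for unequal lengths and DegenerateError if
    any observed value is zero (MAPE undefined).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise LengthMismatchError(
            f"predicted has shape {pred.shape}, observed {obs.shape}"
        )
    n = pred.size
    if n < 2:
        raise LengthMismatchError("need at least 2 pairs")
    if np.any(obs == 0):
        raise DegenerateError("observed contains zeros; MAPE undefined")
    err = pred - obs
    mse = float(np.mean(err**2))
    if np.std(pred) == 0 or np.std(obs) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
    return MetricsReport(
        r=r,
        r_squared=r * r,
        mse=mse,
        mad=float(np.mean(np.abs(err))),
        mape=float(100.0 * np.mean(np.abs(err) / np.abs(obs))),
        bias=float(np.mean(err)),
        pmse=math.sqrt(mse),
        n=n,
    )


def train_test_split(
    data: DataTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[DataTable, DataTable]:
    """Disjoint, exhaustive random partition; train size = round(n·fraction)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    n_train = round(data.n * train_fraction)
    return data.subset(np.sort(perm[:n_train])), data.subset(np.sort(perm[n_train:]))


def head_to_head(
    observed: Sequence[float],
    predictions_a: Sequence[float],
    predictions_b: Sequence[float],
) -> tuple[int, int, int]:
    """Per-row comparison of two predictors by absolute error.

    Returns (count A closer, count B closer, ties); the three counts sum
    to n. Ties are counted separately, never assigned to a side.
    """
    obs = np.asarray(observed, dtype=float)
    a = np.asarray(predictions_a, dtype=float)
    b = np.asarray(predictions_b, dtype=float)
    if not (obs.shape == a.shape == b.shape):
        raise LengthMismatchError("observed and both prediction vectors must align")
    err_a = np.abs(a - obs)
    err_b = np.abs(b - obs)
    return (
        int(np.sum(err_a < err_b)),
        int(np.sum(err_b < err_a)),
        int(np.sum(err_a == err_b)),
    )
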