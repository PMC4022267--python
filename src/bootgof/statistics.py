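"""Residual-based goodness-of-fit statistics.

* ``chi2_statistic`` — weighted residual sum of squares against known
  per-point noise sigma; measures whether residuals are too *big*.
* ``dw_statistic`` — Durbin-Watson ratio of squared adjacent-residual
  differences to squared residuals; measures whether residuals are too
  *correlated* (white residuals give values near 2, positive autocorrelation
  pushes towards 0, negative towards 4).
* ``lhr_statistic`` / ``lhp_statistic`` — difference and sum of two models'
  chi-square values (log-likelihood ratio and product under Gaussian noise);
  the map (chi2_1, chi2_2) -> (LHR, LHP) is a 45-degree rotation scaled by
  sqrt(2), so it preserves cloud geometry.

Adjacent differences in the DW numerator are taken within each measurement
signal only — never across the junction of two signals — while the
denominator runs over all residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import Dataset

__all__ = [
    "StatisticVector",
    "DegenerateFitError",
    "residuals",
    "chi2_statistic",
    "dw_statistic",
    "lhr_statistic",
    "lhp_statistic",
]


class DegenerateFitError(ArithmeticError):
    """All residuals are exactly zero: the DW statistic is undefined.

    Callers may interpret this as a "surprisingly good fit" (it arises e.g.
    when the hyper-flexible interpolant is the tested model).
    """


@dataclass(frozen=True)
class StatisticVector:
    """Named vector of test-statistic values (one point of a cloud)."""

    names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


def _blocks(x) -> tuple[np.ndarray, ...]:
    if isinstance(x, np.ndarray) and x.ndim == 1:
        return (np.asarray(x, dtype=float),)
    return tuple(np.asarray(b, dtype=float) for b in x)


def residuals(dataset: Dataset, predicted) -> tuple[np.ndarray, ...]:
    """Per-signal residuals ``y_i(t_j) - yhat_i(t_j)``, order-preserving."""
    pred = _blocks(predicted)
    if tuple(p.size for p in pred) != dataset.design.block_sizes:
        raise ValueError("predicted shapes do not match the dataset design")
    return tuple(v - p for v, p in zip(dataset.values, pred))


def chi2_statistic(dataset: Dataset, predicted) -> float:
    """Weighted residual sum of squares over all signals and points."""
    pred = _blocks(predicted)
    if tuple(p.size for p in pred) != dataset.design.block_sizes:
        raise ValueError("predicted shapes do not match the dataset design")
    total = 0.0
    for v, s, p in zip(dataset.values, dataset.sigma, pred):
        if not np.all(s > 0):
            raise ValueError("all sigma must be positive")
        total += float(np.sum(((v - p) / s) ** 2))
    return total


def dw_statistic(resid) -> float:
    """Durbin-Watson statistic of a (possibly multi-signal) residual vector.

    Returns a value in ``[0, 4]``.  Raises :class:`DegenerateFitError` when
    every residual is exactly zero.
    """
    blocks = _blocks(resid)
    scale = max((float(np.max(np.abs(b), initial=0.0)) for b in blocks),
                default=0.0)
    if scale == 0.0:
        raise DegenerateFitError(
            "all residuals are exactly zero; DW statistic undefined"
        )
    # rescale before squaring: the ratio is scale-invariant and this keeps
    # tiny residuals (squares would underflow) well-defined
    blocks = [b / scale for b in blocks]
    den = float(sum(np.sum(b ** 2) for b in blocks))
    num = float(sum(np.sum(np.diff(b) ** 2) for b in blocks))
    return num / den


def dw_statistic_rows(resid_matrix: np.ndarray,
                      block_sizes: Sequence[int]) -> np.ndarray:
    """Row-wise DW over a (B, N) residual matrix with per-signal blocks.

    Rows whose residuals are all exactly zero yield NaN (the caller decides
    whether that is an error)."""
    R = np.asarray(resid_matrix, dtype=float)
    scale = np.abs(R).max(axis=1, keepdims=True)
    R = np.divide(R, scale, out=np.zeros_like(R), where=scale > 0)
    den = (R ** 2).sum(axis=1)
    num = np.zeros(len(R))
    start = 0
    for n in block_sizes:
        block = R[:, start:start + n]
        num += (np.diff(block, axis=1) ** 2).sum(axis=1)
        start += n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def lhr_statistic(chi2_m1: float, chi2_m2: float) -> float:
    """Log-likelihood-ratio statistic: tested-model chi2 minus second-model chi2.

    Large positive values mean the tested model fits worse than the second
    model.  Two-tailed testing makes the sign convention immaterial.
    """
    _check_nonneg(chi2_m1, chi2_m2)
    return float(chi2_m1) - float(chi2_m2)


def lhp_statistic(chi2_m1: float, chi2_m2: float) -> float:
    """Log-likelihood-product statistic: sum of the two models' chi2 values."""
    _check_nonneg(chi2_m1, chi2_m2)
    return float(chi2_m1) + float(chi2_m2)


def _check_nonneg(*vals: float) -> None:
    for v in vals:
        if v < 0:
            raise ValueError(f"chi-square values must be >= 0, got {v}")
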