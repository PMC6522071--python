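"""Evaluation statistics for deconvolution benchmarks.

Conventions: ``r_squared`` centers on the *truth* mean (so it can be
negative for estimators worse than the constant predictor), and Pearson
correlation is undefined (``nan``) when either vector is constant — e.g. a
method returning all-zero estimates for a cell type.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["sse", "r_squared", "pearson", "outlier_confusion"]


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError(f"expected two equal-length vectors, got {a.shape} and {b.shape}")
    return a, b


def sse(beta_true, beta_hat) -> float:
    """Sum of squared errors between true and estimated coefficients."""
    a, b = _pair(beta_true, beta_hat)
    d = a - b
    return float(d @ d)


def r_squared(beta_true, beta_hat) -> float:
    """Coefficient of determination against the truth mean.

    ``1 - SSE / sum((true - mean(true))^2)``; returns ``nan`` for constant
    truth, and can be negative for estimates worse than the truth mean.
    """
    a, b = _pair(beta_true, beta_hat)
    denom = float(np.sum((a - a.mean()) ** 2))
    if denom == 0.0:
        return float("nan")
    return 1.0 - sse(a, b) / denom


def pearson(beta_true, beta_hat) -> float:
    """Product-moment correlation; ``nan`` if either vector is constant."""
    a, b = _pair(beta_true, beta_hat)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0 or a.size < 2:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def outlier_confusion(true_index, detected_index, n: int) -> tuple[float, float]:
    """True/false positive rates of outlier detection.

    ``tpr = |true ∩ detected| / |true|`` (``nan`` for an empty truth set) and
    ``fpr = |detected \\ true| / (n - |true|)``.
    """
    true_set = set(int(i) for i in true_index)
    det_set = set(int(i) for i in detected_index)
    universe = set(range(n))
    if not true_set <= universe or not det_set <= universe:
        raise ValueError("index sets must be subsets of range(n)")
    fp = len(det_set - true_set)
    fpr = fp / (n - len(true_set)) if n > len(true_set) else float("nan")
    if not true_set:
        return float("nan"), fpr
    tpr = len(true_set & det_set) / len(true_set)
    return tpr, fpr
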