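"""Adaptive least trimmed squares (aLTS) over non-negative least squares.

The estimator alternates between (a) refitting a least-squares model on the
observations currently believed clean and (b) re-estimating how many
observations are outliers.  Two integer sequences bracket the unknown outlier
count: an overestimate ``n_over`` obtained by thresholding absolute residuals
at a multiple ``k`` of their median, and an underestimate ``n_under`` grown
geometrically by ``alpha2`` from an initial fraction ``alpha1`` of the first
overestimate.  The overestimate is non-increasing and the underestimate
non-decreasing, so the two meet after at most
``floor(-log(alpha1)/log(alpha2)) + 2`` refits regardless of the data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _lawson_hanson

logger = logging.getLogger(__name__)

__all__ = [
    "ALTSParams",
    "TrimState",
    "ALTSFit",
    "nnls_solve",
    "update_overestimate",
    "update_underestimate",
    "max_iterations",
    "alts_fit",
]


def _check_alphas(alpha1: float, alpha2: float) -> None:
    if not (0.0 < alpha1 < 1.0):
        raise ValueError(f"alpha1 must lie in (0, 1), got {alpha1}")
    if not alpha2 > 1.0:
        raise ValueError(f"alpha2 must exceed 1, got {alpha2}")


@dataclass(frozen=True)
class ALTSParams:
    """Knobs of the trimmed fit.

    Parameters
    ----------
    k
        Sensitivity multiplier on the residual median used from the second
        iteration on.  Smaller ``k`` flags more observations.  Normally chosen
        per sample by BIC* tuning (:func:`fardeep.tuning.tune_k`); the default
        only applies when tuning is bypassed.
    alpha1
        Fraction of the first overestimate used as the initial underestimate.
    alpha2
        Geometric growth factor of the underestimate.
    nonneg
        Solve NNLS on the retained rows (the deconvolution setting); if
        false, ordinary least squares.
    intercept
        Append a sign-unconstrained intercept column (off by default; the
        mixture model has none).
    max_outlier_frac
        Optional cap on the trimmed fraction.  Regardless of its value the
        retained count never drops below ``p + 1``.
    median_floor
        Absolute floor under the residual median below which the fit is
        declared exact and trimming stops.  ``None`` selects
        ``1e-12 * max(1, median(|y|))`` at fit time.
    """

    k: float = 6.0
    alpha1: float = 0.1
    alpha2: float = 1.5
    nonneg: bool = True
    intercept: bool = False
    max_outlier_frac: float | None = None
    median_floor: float | None = None

    def __post_init__(self) -> None:
        _check_alphas(self.alpha1, self.alpha2)
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.max_outlier_frac is not None and not (0.0 < self.max_outlier_frac < 1.0):
            raise ValueError("max_outlier_frac must lie in (0, 1)")
        if self.median_floor is not None and not self.median_floor > 0:
            raise ValueError("median_floor must be positive")


@dataclass
class TrimState:
    """Snapshot of one trimming iteration (kept for diagnostics/tests)."""

    j: int
    n_over: int
    n_under: int
    r: np.ndarray
    r_med: float


@dataclass
class ALTSFit:
    """Result of one adaptive trimmed fit."""

    beta: np.ndarray
    outlier_index: np.ndarray
    n_outliers: int
    residuals: np.ndarray
    n_iter: int
    converged: bool
    retained_index: np.ndarray
    intercept_: float = 0.0
    trace: list[TrimState] = field(default_factory=list)

    @property
    def fitted(self) -> np.ndarray:
        """Fitted values implied by ``residuals`` (y - r)."""
        return self._y - self.residuals

    _y: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def nnls_solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Non-negative least squares via the Lawson-Hanson active-set method.

    Returns ``argmin ||y - X b||^2 subject to b >= 0``; deterministic for a
    fixed input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1 or X.shape[0] < 1:
        raise ValueError(f"design must be a 2-d matrix with n,p >= 1, got shape {X.shape}")
    if y.shape != (X.shape[0],):
        raise ValueError("response length does not match design rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in NNLS input")
    beta, _ = _lawson_hanson(X, y)
    return beta


def update_overestimate(
    abs_residuals: np.ndarray,
    r_med: float,
    k: float,
    j: int,
    n_over_prev: int | None = None,
) -> int:
    """Overestimate of the outlier count at iteration ``j``.

    First iteration counts ``|r_i| > r_med`` (no ``k`` factor); later
    iterations count ``|r_i| > k * r_med`` and clamp by the previous value so
    the sequence is non-increasing.  Strict inequality at the threshold.
    """
    if j < 1:
        raise ValueError(f"iteration index must be >= 1, got {j}")
    if j == 1:
        return int(np.count_nonzero(abs_residuals > r_med))
    if n_over_prev is None:
        raise ValueError("previous overestimate required for j >= 2")
    count = int(np.count_nonzero(abs_residuals > k * r_med))
    return min(count, n_over_prev)


def update_underestimate(
    n_over_j: int,
    n_under_prev: int | None,
    alpha1: float,
    alpha2: float,
    j: int,
) -> int:
    """Underestimate of the outlier count at iteration ``j``.

    ``ceil(alpha1 * n_over)`` at the first iteration, then grown by
    ``alpha2`` and clamped by the current overestimate.
    """
    _check_alphas(alpha1, alpha2)
    if j < 1:
        raise ValueError(f"iteration index must be >= 1, got {j}")
    if j == 1:
        return math.ceil(alpha1 * n_over_j)
    if n_under_prev is None:
        raise ValueError("previous underestimate required for j >= 2")
    return min(math.ceil(alpha2 * n_under_prev), n_over_j)


def max_iterations(alpha1: float, alpha2: float) -> int:
    """Worst-case number of trimming iterations: ``floor(-log a1 / log a2) + 2``.

    With the defaults (0.1, 1.5) this evaluates to 7.
    """
    _check_alphas(alpha1, alpha2)
    return math.floor(-math.log(alpha1) / math.log(alpha2)) + 2


def _augment(X: np.ndarray, params: ALTSParams) -> np.ndarray:
    """Append intercept column(s); NNLS gets a +1/-1 pair so the intercept
    stays sign-unconstrained while the cell-type coefficients do not."""
    n = X.shape[0]
    ones = np.ones((n, 1))
    if params.nonneg:
        return np.hstack([X, ones, -ones])
    return np.hstack([X, ones])


def _solve(X: np.ndarray, y: np.ndarray, nonneg: bool) -> np.ndarray:
    if nonneg:
        return nnls_solve(X, y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def alts_fit(
    X: np.ndarray,
    y: np.ndarray,
    params: ALTSParams | None = None,
    *,
    _cache: dict | None = None,
) -> ALTSFit:
    """Fit the adaptive least trimmed squares model.

    Starts from a fit on all ``n`` observations, then alternates residual
    thresholding and refitting until the outlier-count over- and
    underestimates agree.  The observations removed at convergence are the
    detected outliers; ties among equal absolute residuals are broken toward
    the lowest row index, making the procedure deterministic.

    ``_cache`` optionally maps removal-index tuples to previously computed
    coefficient vectors so that a tuning sweep over ``k`` can share solves; it
    never changes the result.
    """
    if params is None:
        params = ALTSParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-d")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("response length does not match design rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in input")
    p_eff = p + (1 if params.intercept else 0)
    if n <= p_eff:
        raise ValueError(f"need n > p ({n} rows, {p_eff} parameters)")

    Xd = _augment(X, params) if params.intercept else X
    cap = n - p_eff - 1
    if params.max_outlier_frac is not None:
        cap = min(cap, math.floor(n * params.max_outlier_frac))
    floor_val = params.median_floor
    if floor_val is None:
        floor_val = 1e-12 * max(1.0, float(np.median(np.abs(y))))

    def predict(b: np.ndarray) -> np.ndarray:
        return Xd @ b

    def extract(b: np.ndarray) -> tuple[np.ndarray, float]:
        if not params.intercept:
            return b, 0.0
        if params.nonneg:
            return b[:p], float(b[p] - b[p + 1])
        return b[:p], float(b[p])

    def solve_removed(removed: tuple[int, ...]) -> np.ndarray:
        if _cache is not None and removed in _cache:
            return _cache[removed]
        keep = np.setdiff1d(np.arange(n), np.asarray(removed, dtype=int), assume_unique=False)
        b = _solve(Xd[keep], y[keep], params.nonneg)
        if _cache is not None:
            _cache[removed] = b
        return b

    removed: tuple[int, ...] = ()
    b_full = solve_removed(removed)
    r = y - predict(b_full)

    n_over: int | None = None
    n_under: int | None = None
    n_iter = 0
    converged = False
    trace: list[TrimState] = []
    jmax = max_iterations(params.alpha1, params.alpha2)
    beta_aug = b_full

    for j in range(1, jmax + 1):
        abs_r = np.abs(r)
        r_med = float(np.median(abs_r))
        if r_med <= floor_val:
            # Residual scale is numerically zero: the current fit explains the
            # retained data exactly; declare no further outliers.
            converged = True
            break
        n_over = update_overestimate(abs_r, r_med, params.k, j, n_over)
        n_under = update_underestimate(n_over, n_under, params.alpha1, params.alpha2, j)
        if n_under > cap:
            logger.warning(
                "trimming capped at %d observations (requested %d) to keep >= p+1 rows",
                cap,
                n_under,
            )
            n_under = cap
        # N_under largest |residuals|; stable sort on -|r| breaks ties toward
        # the lowest observation index.
        order = np.argsort(-abs_r, kind="stable")
        removed = tuple(sorted(int(i) for i in order[:n_under]))
        beta_aug = solve_removed(removed)
        r = y - predict(beta_aug)
        trace.append(TrimState(j=j, n_over=n_over, n_under=n_under, r=r.copy(), r_med=r_med))
        n_iter = j
        if n_over == n_under:
            converged = True
            break

    beta, icpt = extract(beta_aug)
    outlier_index = np.asarray(removed, dtype=int)
    retained = np.setdiff1d(np.arange(n), outlier_index)
    return ALTSFit(
        beta=beta,
        outlier_index=outlier_index,
        n_outliers=len(outlier_index),
        residuals=r,
        n_iter=n_iter,
        converged=converged,
        retained_index=retained,
        intercept_=icpt,
        trace=trace,
        _y=y,
    )
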