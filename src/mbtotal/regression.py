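"""Least-squares engines for the two regime models.

Three fitting routes are provided: ordinary least squares for the standard
case, weighted least squares when per-unit error variances are known, and
ridge-augmented least squares for the super-collinear case that arises when
the second-call sub-sample is smaller than the number of regressors
(n'2 <= p), where X'X is singular and the normal equations have no unique
solution.  Ridge replaces H = X'X by H(v) = H + v I with tuning parameter
v > 0, which is invertible for any v > 0 regardless of rank.

The module also computes the admissible tuning range: ridge prediction of
the non-respondent regime beats unpenalised prediction in mean squared
error for 0 < v < 2 * [-min(0, psi2)], where psi2 is the smallest
eigenvalue of H^{-1} - beta beta' / sigma^2.  When that matrix is positive
semi-definite the range is empty and no ridge value helps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .errors import (
    DegreesOfFreedomError,
    InvalidWeightsError,
    SelectionError,
    SuperCollinearityError,
)

__all__ = [
    "LinearFit",
    "RidgeRange",
    "fit_ols",
    "fit_wls",
    "fit_prr",
    "ridge_admissible_range",
    "select_tuning",
    "estimate_error_variance",
    "COND_THRESHOLD",
]

# Condition number of H above which the normal equations are treated as
# numerically singular and the super-collinearity path is taken.
COND_THRESHOLD = 1e12


@dataclass
class LinearFit:
    """Result of one least-squares fit.

    ``b`` coefficient vector (intercept first); ``H`` the cross-product
    matrix actually inverted (ridge-augmented for method "prr"); ``v`` the
    ridge tuning parameter (0 for OLS/WLS); ``sigma_sq_hat`` the estimated
    error variance (``None`` when the fit is saturated); ``method`` one of
    "ols", "wls", "prr"; ``n_obs`` the fitting-sample size.  For "prr" the
    variance estimate uses divisor n and is approximate
    (``sigma_sq_approx`` is then True).
    """

    b: np.ndarray
    H: np.ndarray
    v: float
    sigma_sq_hat: Optional[float]
    method: str
    n_obs: int
    sigma_sq_approx: bool = False


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    return X, y


def _solve_spd(H: np.ndarray, g: np.ndarray, context: str) -> np.ndarray:
    """Solve H b = g for symmetric positive-definite H with a condition check."""
    try:
        c, low = scipy.linalg.cho_factor(H)
    except np.linalg.LinAlgError as exc:
        raise SuperCollinearityError(
            f"{context}: X'X is singular (not of full rank); "
            "use fit_prr with v > 0 to obtain a ridge solution"
        ) from exc
    if np.linalg.cond(H) > COND_THRESHOLD:
        raise SuperCollinearityError(
            f"{context}: X'X is numerically ill-conditioned "
            f"(cond > {COND_THRESHOLD:.0e}); use fit_prr with v > 0"
        )
    return scipy.linalg.cho_solve((c, low), g)


def fit_ols(X_s: np.ndarray, y_s: np.ndarray) -> LinearFit:
    """Ordinary least squares via the normal equations (X'X) b = X'y."""
    X_s, y_s = _check_xy(X_s, y_s)
    n, q = X_s.shape
    if n < q:
        raise SuperCollinearityError(
            f"fit_ols: {n} observations for {q} coefficients; "
            "X'X cannot be of full rank — use fit_prr"
        )
    H = X_s.T @ X_s
    b = _solve_spd(H, X_s.T @ y_s, "fit_ols")
    sigma_sq_hat = None
    if n > q:
        rss = float(np.sum((y_s - X_s @ b) ** 2))
        sigma_sq_hat = rss / (n - q)
    return LinearFit(b=b, H=H, v=0.0, sigma_sq_hat=sigma_sq_hat,
                     method="ols", n_obs=n)


def fit_wls(X_s: np.ndarray, y_s: np.ndarray, V_s: np.ndarray) -> LinearFit:
    """Weighted least squares with known diagonal error variances ``V_s``.

    b = (X' V^{-1} X)^{-1} X' V^{-1} y.  Reduces to OLS for any constant
    variance vector.
    """
    X_s, y_s = _check_xy(X_s, y_s)
    V_s = np.asarray(V_s, dtype=float)
    if V_s.ndim == 2:
        V_s = np.diag(V_s)
    V_s = V_s.ravel()
    if V_s.shape[0] != X_s.shape[0]:
        raise InvalidWeightsError("V_s must have one variance per observation")
    if (V_s <= 0).any():
        raise InvalidWeightsError("all variance entries must be strictly positive")
    n, q = X_s.shape
    if n < q:
        raise SuperCollinearityError(
            f"fit_wls: {n} observations for {q} coefficients — use fit_prr"
        )
    Xw = X_s / V_s[:, None]
    H = X_s.T @ Xw
    b = _solve_spd(H, Xw.T @ y_s, "fit_wls")
    sigma_sq_hat = None
    if n > q:
        wrss = float(np.sum((y_s - X_s @ b) ** 2 / V_s))
        sigma_sq_hat = wrss / (n - q)
    return LinearFit(b=b, H=H, v=0.0, sigma_sq_hat=sigma_sq_hat,
                     method="wls", n_obs=n)


def fit_prr(X_s: np.ndarray, y_s: np.ndarray, v: float) -> LinearFit:
    """Ridge-augmented least squares: b = (X'X + v I)^{-1} X'y.

    Well defined for any v > 0 even when n < p+1 (super-collinearity).
    With v = 0 and a full-rank system it coincides with :func:`fit_ols`.
    """
    X_s, y_s = _check_xy(X_s, y_s)
    if v < 0:
        raise ValueError("ridge tuning parameter v must be nonnegative")
    n, q = X_s.shape
    H0 = X_s.T @ X_s
    if v == 0:
        return fit_ols(X_s, y_s)
    H = H0 + v * np.eye(q)
    b = _solve_spd(H, X_s.T @ y_s, "fit_prr")
    rss = float(np.sum((y_s - X_s @ b) ** 2))
    return LinearFit(b=b, H=H, v=float(v), sigma_sq_hat=rss / n,
                     method="prr", n_obs=n, sigma_sq_approx=True)


@dataclass
class RidgeRange:
    """Admissible ridge tuning range (0, upper).

    ``psi2`` is the minimum eigenvalue of H^{-1} - beta beta'/sigma^2;
    ``upper = 2 * (-min(0, psi2))``, zero exactly when that matrix is
    positive semi-definite (in which case no positive v improves on OLS).
    """

    psi2: float
    upper: float


def ridge_admissible_range(
    H: np.ndarray,
    beta2: np.ndarray,
    sigma2_sq: float,
) -> RidgeRange:
    """Range of tuning values for which ridge prediction beats OLS in MSE."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    beta2 = np.asarray(beta2, dtype=float).ravel()
    if sigma2_sq <= 0:
        raise ValueError("sigma2_sq must be strictly positive")
    if H.shape[0] != H.shape[1] or H.shape[0] != beta2.shape[0]:
        raise ValueError("H must be square and conformable with beta2")
    try:
        Hinv = scipy.linalg.inv(H)
    except scipy.linalg.LinAlgError as exc:
        raise SuperCollinearityError(
            "ridge_admissible_range: H is singular, the range is undefined"
        ) from exc
    M = Hinv - np.outer(beta2, beta2) / sigma2_sq
    psi2 = float(scipy.linalg.eigh(M, eigvals_only=True)[0])
    return RidgeRange(psi2=psi2, upper=2.0 * (-min(0.0, psi2)))


def _loocv_error(X: np.ndarray, y: np.ndarray, v: float) -> float:
    """Leave-one-out CV squared prediction error of the ridge fit at v.

    Uses the closed form e_i = (y_i - yhat_i) / (1 - h_ii) with h the
    ridge hat matrix; observations with h_ii ~ 1 make v infeasible.
    """
    n, q = X.shape
    H = X.T @ X + v * np.eye(q)
    try:
        Hinv = scipy.linalg.inv(H)
    except scipy.linalg.LinAlgError:
        return np.inf
    h = np.einsum("ij,jk,ik->i", X, Hinv, X)
    resid = y - X @ (Hinv @ (X.T @ y))
    denom = 1.0 - h
    if (np.abs(denom) < 1e-12).any():
        return np.inf
    return float(np.mean((resid / denom) ** 2))


def select_tuning(
    X_s: np.ndarray,
    y_s: np.ndarray,
    grid: np.ndarray,
    range_cap: Optional[float] = None,
) -> float:
    """Choose the ridge tuning parameter by leave-one-out cross-validation.

    Returns the grid value minimising the LOOCV squared prediction error of
    the ridge fit; ties resolve to the smallest value.  When ``range_cap``
    is given (e.g. the plug-in admissible upper bound) the grid is first
    truncated to (0, range_cap].
    """
    X_s, y_s = _check_xy(X_s, y_s)
    grid = np.sort(np.asarray(grid, dtype=float).ravel())
    if grid.size == 0:
        raise SelectionError("tuning grid is empty")
    if X_s.shape[0] < 2:
        raise SelectionError("need at least 2 observations for LOOCV")
    if range_cap is not None:
        grid = grid[(grid > 0) & (grid <= range_cap)]
        if grid.size == 0:
            raise SelectionError(
                f"no grid value lies in the admissible range (0, {range_cap:g}]"
            )
    errors = np.array([_loocv_error(X_s, y_s, v) for v in grid])
    if not np.isfinite(errors).any():
        raise SelectionError("LOOCV error undefined for every grid value")
    return float(grid[int(np.argmin(errors))])


def estimate_error_variance(
    fit: LinearFit,
    X_s: np.ndarray,
    y_s: np.ndarray,
) -> float:
    """Estimate the model error variance from fit residuals.

    RSS/(n-p-1) for OLS, weighted RSS/(n-p-1) for WLS (requires
    n > p+1), and the approximate RSS/n for ridge fits, which have no
    exact residual degrees of freedom.
    """
    X_s, y_s = _check_xy(X_s, y_s)
    n, q = X_s.shape
    resid = y_s - X_s @ fit.b
    if fit.method == "prr":
        return float(np.sum(resid**2)) / n
    if n <= q:
        raise DegreesOfFreedomError(
            f"need more than {q} observations for an unbiased variance "
            f"estimate, got {n}"
        )
    if fit.method == "wls":
        # Recover the weights from the fit's H: not stored, so require the
        # caller to pass pre-whitened data or use the fit-time estimate.
        if fit.sigma_sq_hat is not None:
            return float(fit.sigma_sq_hat)
        raise DegreesOfFreedomError("WLS fit carries no variance estimate")
    return float(np.sum(resid**2)) / (n - q)
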