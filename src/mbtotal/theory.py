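"""Closed-form model bias, variance and MSE of the total predictors.

All formulas condition on the realised sample draw (the design indices are
fixed; expectations run over the model errors only).  Design-averaged
versions are obtained by Monte-Carlo over fresh SRSWOR draws, since no
closed form over the design is available.

Conventions.  ``H_s1`` is the respondent-sample cross-product matrix
x_s1' x_s1 and ``H_s2p`` the sub-sample one.  The respondent-only
predictor has model bias W2' x2 (beta_r - beta_nr) and model variance

    sigma1^2 (n1 + a1' H_s1^{-1} a1) + sigma2^2 (a2' H_s1^{-1} a2)

with a1 = x_{s1bar}' W_{s1bar} and a2 = x_2' W_2.  The sub-sampling
predictor is model-unbiased with model variance

    n1 sigma1^2 + n'2 sigma2^2
      + sigma1^2 a1' H_s1^{-1} a1 + sigma2^2 a2p' H_s2p^{-1} a2p

with a2p = x_{s2pbar}' W_{s2pbar}.  Note the leading n1/n'2 terms make
this the variance of the *estimator* T-hat rather than of the prediction
error T-hat - T; the two differ because the observed sample sum is part of
both the estimator and the estimand.  ``empirical_prediction_moments``
reports the prediction-error moments directly, so both views are
available without silently altering the printed formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import logging

import numpy as np
import scipy.linalg

from .errors import InvalidSpecError, SuperCollinearityError
from .regression import COND_THRESHOLD
from .estimators import SampleDraw, TotalEstimate, make_draw
from .population import FinitePopulation, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorDecomposition",
    "bias_respondents_only",
    "mse_respondents_only",
    "var_subsampling",
    "expected_var_full",
    "expected_var_subsampling",
    "empirical_prediction_moments",
]


@dataclass
class ErrorDecomposition:
    """Model bias / variance / MSE of a total predictor.

    ``mse_m = bias_m**2 + var_m`` always.  ``expected_var_d`` holds a
    design-averaged variance when one was computed, else None.  ``mc_reps``
    is 0 for purely analytic decompositions; ``bias_se`` is the Monte-Carlo
    standard error of the bias for empirical ones.
    """

    bias_m: float
    var_m: float
    mse_m: float
    expected_var_d: Optional[float] = None
    mc_reps: int = 0
    bias_se: Optional[float] = None


def _quad_form(a: np.ndarray, H: np.ndarray, context: str) -> float:
    """a' H^{-1} a via a Cholesky solve, with the package-wide
    condition-number criterion for numerical singularity."""
    if a.size == 0:
        return 0.0
    try:
        c, low = scipy.linalg.cho_factor(H)
    except np.linalg.LinAlgError as exc:
        raise SuperCollinearityError(f"{context}: H is singular") from exc
    if np.linalg.cond(H) > COND_THRESHOLD:
        raise SuperCollinearityError(
            f"{context}: H is numerically ill-conditioned"
        )
    return float(a @ scipy.linalg.cho_solve((c, low), a))


def bias_respondents_only(
    W2: np.ndarray,
    X2: np.ndarray,
    beta1: np.ndarray,
    beta2: np.ndarray,
) -> float:
    """Model bias of the respondent-only predictor: W2' X2 (beta1 - beta2).

    Vanishes when the two regimes share one coefficient vector, or when
    the non-respondent stratum is empty.
    """
    W2 = np.asarray(W2, dtype=float).ravel()
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    beta1 = np.asarray(beta1, dtype=float).ravel()
    beta2 = np.asarray(beta2, dtype=float).ravel()
    if W2.size == 0:
        return 0.0
    if X2.shape != (W2.size, beta1.size) or beta1.shape != beta2.shape:
        raise InvalidSpecError("bias_respondents_only: shapes do not conform")
    return float(W2 @ (X2 @ (beta1 - beta2)))


def _geometry(pop: FinitePopulation, draw: SampleDraw):
    X, W = pop.X, pop.W
    a1 = X[draw.s1_bar].T @ W[draw.s1_bar] if draw.s1_bar.size else np.zeros(X.shape[1])
    H_s1 = X[draw.s1].T @ X[draw.s1]
    return X, W, a1, H_s1


def mse_respondents_only(
    draw: SampleDraw,
    pop: FinitePopulation,
    sigma1_sq: float,
    sigma2_sq: float,
    beta1: np.ndarray,
    beta2: np.ndarray,
) -> ErrorDecomposition:
    """Model bias, variance and MSE of the respondent-only predictor,
    conditional on the draw."""
    if sigma1_sq < 0 or sigma2_sq < 0:
        raise InvalidSpecError("variances must be nonnegative")
    X, W, a1, H_s1 = _geometry(pop, draw)
    u2 = np.flatnonzero(draw.R == 0)
    a2 = X[u2].T @ W[u2] if u2.size else np.zeros(X.shape[1])
    var_m = sigma1_sq * (draw.n1 + _quad_form(a1, H_s1, "mse_respondents_only")) \
        + sigma2_sq * _quad_form(a2, H_s1, "mse_respondents_only")
    bias = bias_respondents_only(W[u2], X[u2], beta1, beta2)
    return ErrorDecomposition(bias_m=bias, var_m=var_m, mse_m=bias**2 + var_m)


def var_subsampling(
    draw: SampleDraw,
    pop: FinitePopulation,
    sigma1_sq: float,
    sigma2_sq: float,
) -> float:
    """Model variance of the sub-sampling predictor, conditional on the draw.

    n1 s1^2 + n'2 s2^2 + s1^2 a1'H_s1^{-1}a1 + s2^2 a2p'H_s2p^{-1}a2p.
    """
    if sigma1_sq < 0 or sigma2_sq < 0:
        raise InvalidSpecError("variances must be nonnegative")
    X, W, a1, H_s1 = _geometry(pop, draw)
    value = sigma1_sq * draw.n1 + sigma2_sq * draw.n2_prime
    value += sigma1_sq * _quad_form(a1, H_s1, "var_subsampling")
    if draw.s2_prime_bar.size:
        a2p = X[draw.s2_prime_bar].T @ W[draw.s2_prime_bar]
        H_s2p = X[draw.s2_prime].T @ X[draw.s2_prime]
        value += sigma2_sq * _quad_form(a2p, H_s2p, "var_subsampling")
    return float(value)


def expected_var_full(
    pop: FinitePopulation,
    n: int,
    sigma_sq: float,
    reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> float:
    """Design-averaged model variance of the full-response predictor.

    Monte-Carlo average over SRSWOR draws of
    sigma^2 * [ a' H_s^{-1} a + W_sbar' W_sbar ].
    """
    from .montecarlo import draw_srswor

    rng = np.random.default_rng(seed)
    X, W = pop.X, pop.W
    vals = []
    rejected = 0
    while len(vals) < reps:
        s = draw_srswor(pop.N, n, rng)
        mask = np.ones(pop.N, dtype=bool)
        mask[s] = False
        s_bar = np.flatnonzero(mask)
        a = X[s_bar].T @ W[s_bar] if s_bar.size else np.zeros(X.shape[1])
        try:
            q = _quad_form(a, X[s].T @ X[s], "expected_var_full")
        except SuperCollinearityError:
            rejected += 1
            if rejected > 100 * reps:
                raise
            continue
        vals.append(sigma_sq * (q + float(W[s_bar] @ W[s_bar])))
    if rejected:
        logger.info("expected_var_full: rejected %d singular draws", rejected)
    return float(np.mean(vals))


def expected_var_subsampling(
    pop: FinitePopulation,
    design: SimulationConfig,
    sigma1_sq: float,
    sigma2_sq: float,
    reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> float:
    """Design-averaged model variance of the sub-sampling predictor.

    Monte-Carlo over fresh first-call samples and second-call sub-samples;
    draws whose fitting matrices are singular are rejected, resampled and
    counted in the log.
    """
    if reps < 1:
        raise InvalidSpecError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    vals = []
    rejected = 0
    while len(vals) < reps:
        draw = make_draw(pop, design.n, design.k, rng)
        try:
            vals.append(var_subsampling(draw, pop, sigma1_sq, sigma2_sq))
        except SuperCollinearityError:
            rejected += 1
            if rejected > 100 * reps:
                raise
    if rejected:
        logger.info(
            "expected_var_subsampling: rejected %d singular draws", rejected
        )
    return float(np.mean(vals))


def empirical_prediction_moments(
    pop: FinitePopulation,
    draw: SampleDraw,
    fitter: Callable[[FinitePopulation, SampleDraw], TotalEstimate],
    error_reps: int = 2000,
    seed: int | np.random.Generator = 0,
) -> ErrorDecomposition:
    """Monte-Carlo moments of the prediction error, holding the draw fixed.

    Requires a synthetic population carrying its generating truth in
    ``metadata['truth']``.  The model errors are redrawn ``error_reps``
    times around the fixed conditional means, the fit and prediction are
    recomputed each time, and the empirical bias, variance and MSE of
    (estimate - T_y) are returned, together with the Monte-Carlo standard
    error of the bias.  This is the independent audit of the closed-form
    bias and unbiasedness results.
    """
    truth = pop.metadata.get("truth")
    if truth is None:
        raise InvalidSpecError(
            "empirical_prediction_moments needs a synthetic population "
            "with known generating parameters in metadata['truth']"
        )
    rng = np.random.default_rng(seed)
    mean = truth["mean"]
    sd = truth["unit_sd"]
    devs = np.empty(error_reps)
    work = FinitePopulation(
        y=pop.y.copy(), X=pop.X, R=pop.R, W=pop.W, metadata=pop.metadata
    )
    for r in range(error_reps):
        work.y = mean + sd * rng.standard_normal(pop.N)
        t_y = float(work.W @ work.y)
        est = fitter(work, draw)
        devs[r] = est.total - t_y
    bias = float(devs.mean())
    var = float(devs.var(ddof=1)) if error_reps > 1 else 0.0
    return ErrorDecomposition(
        bias_m=bias,
        var_m=var,
        mse_m=bias**2 + var,
        mc_reps=error_reps,
        bias_se=float(np.sqrt(var / error_reps)) if error_reps > 1 else None,
    )
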