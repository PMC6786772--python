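"""Prediction estimators of the finite-population total.

Three predictors, in increasing order of robustness to non-ignorable
non-response:

* ``predict_total_full`` — the classical model-based predictor under full
  response: observed sample sum plus model predictions for every
  non-sampled unit.
* ``predict_total_respondents_only`` — the naive predictor that fits the
  respondent regime only and extrapolates it to the whole population,
  including the entire non-respondent stratum.  Model-biased by
  W2' x2 (beta_r - beta_nr) when the regimes differ.
* ``predict_total_subsampling`` — the sub-sampling predictor: after
  first-call non-response, a fraction 1/k of the n2 non-respondents is
  re-contacted with a stronger interview mode and fully observed; the
  non-respondent regime is fitted on that second-call sub-sample and used
  to predict the remaining non-respondent units.  Model-unbiased when both
  regime fits satisfy the OLS assumptions.

When the sub-sample is too small for OLS (n'2 <= p+1) the regime-2 fit
switches to ridge, giving the partially-ridge-regression (PRR) variant of
the sub-sampling predictor: ridge coefficients are used for the
non-respondent regime only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import EstimationError, InvalidSpecError, SuperCollinearityError
from .population import FinitePopulation
from .regression import LinearFit, fit_ols, fit_prr, fit_wls, select_tuning

__all__ = [
    "SampleDraw",
    "TotalEstimate",
    "RidgePolicy",
    "subsample_size",
    "make_draw",
    "predict_total_full",
    "predict_total_respondents_only",
    "predict_total_subsampling",
    "auto_fit_and_predict",
    "DEFAULT_TUNING_GRID",
]

# Default grid for ridge tuning selection, log-spaced over eight decades.
DEFAULT_TUNING_GRID = np.logspace(-4.0, 4.0, 17)


def subsample_size(n2: int, k: float) -> int:
    """Second-call sub-sample size: n2/k rounded to the nearest integer
    (round-half-to-even), at least 1 when n2 > 0."""
    if n2 == 0:
        return 0
    return max(1, round(n2 / k))


@dataclass
class SampleDraw:
    """A first-call sample with its response split and second-call sub-sample.

    ``s`` is the first-call sample; ``s1``/``s2`` its respondent and
    non-respondent parts; ``s2_prime`` the second-call sub-sample of
    ``s2`` of size ~ n2/k.  Complements are taken within the population of
    ``N`` units with stratum indicator ``R``: ``s_bar = U - s``,
    ``s1_bar = U1 - s1`` (non-sampled respondents) and
    ``s2_prime_bar = U2 - s2_prime`` (every non-respondent unit not
    observed on the second call, sampled or not).
    """

    N: int
    R: np.ndarray
    s: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    s2_prime: np.ndarray
    k: float = 1.0
    s_bar: np.ndarray = field(init=False)
    s1_bar: np.ndarray = field(init=False)
    s2_prime_bar: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("s", "s1", "s2", "s2_prime"):
            arr = np.asarray(getattr(self, name), dtype=np.intp).ravel()
            setattr(self, name, arr)
            if arr.size and (arr.min() < 0 or arr.max() >= self.N):
                raise InvalidSpecError(f"{name} contains out-of-range indices")
        self.R = np.asarray(self.R)
        if self.R.shape[0] != self.N:
            raise InvalidSpecError("R must cover the whole population")
        s_sorted = np.sort(self.s)
        if not np.array_equal(np.sort(np.concatenate([self.s1, self.s2])), s_sorted):
            raise InvalidSpecError("s1 and s2 must partition s")
        if not np.isin(self.s2_prime, self.s2).all():
            raise InvalidSpecError("s2_prime must be a subset of s2")
        mask = np.ones(self.N, dtype=bool)
        mask[self.s] = False
        self.s_bar = np.flatnonzero(mask)
        u1 = np.flatnonzero(self.R == 1)
        self.s1_bar = np.setdiff1d(u1, self.s1, assume_unique=False)
        u2 = np.flatnonzero(self.R == 0)
        self.s2_prime_bar = np.setdiff1d(u2, self.s2_prime, assume_unique=False)

    @property
    def n(self) -> int:
        return self.s.size

    @property
    def n1(self) -> int:
        return self.s1.size

    @property
    def n2(self) -> int:
        return self.s2.size

    @property
    def n2_prime(self) -> int:
        return self.s2_prime.size


def make_draw(
    pop: FinitePopulation,
    n: int,
    k: float,
    rng: np.random.Generator,
) -> SampleDraw:
    """Draw a first-call SRSWOR sample of size n, split it by the
    population response indicator, and sub-sample the non-respondent part
    at rate 1/k."""
    from .montecarlo import draw_srswor, split_by_response, subsample_nonrespondents

    R = pop.R
    if R is None:
        raise InvalidSpecError("population needs a response indicator; "
                               "see assign_response_by_quantile")
    s = draw_srswor(pop.N, n, rng)
    s1, s2 = split_by_response(s, R)
    s2p = subsample_nonrespondents(s2, k, rng)
    return SampleDraw(N=pop.N, R=R, s=s, s1=s1, s2=s2, s2_prime=s2p, k=k)


@dataclass
class TotalEstimate:
    """A predicted population total and its four additive components.

    components = (observed respondent sum, predicted non-sampled
    respondent part, observed second-call sum, predicted remaining
    non-respondent part).  ``total`` always equals their sum.
    """

    total: float
    components: tuple[float, float, float, float]
    method: dict

    def __post_init__(self) -> None:
        assert np.isclose(self.total, sum(self.components), rtol=1e-9, atol=1e-6)

    def to_record(self) -> dict:
        rec = {"total": self.total}
        rec.update(
            zip(
                ("observed_resp", "predicted_resp",
                 "observed_subsample", "predicted_nonresp"),
                self.components,
            )
        )
        rec.update(self.method)
        return rec


def _wx_sum(pop: FinitePopulation, idx: np.ndarray) -> np.ndarray:
    """Weighted column sum of X over the index set: sum_i W_i x_i."""
    if idx.size == 0:
        return np.zeros(pop.X.shape[1])
    return pop.W[idx] @ pop.X[idx]


def _wy_sum(pop: FinitePopulation, idx: np.ndarray) -> float:
    if idx.size == 0:
        return 0.0
    return float(pop.W[idx] @ pop.y[idx])


def predict_total_full(
    pop: FinitePopulation,
    s: np.ndarray,
    fit: LinearFit,
) -> TotalEstimate:
    """Full-response predictor: sum over the sample plus model predictions
    W' x b over the non-sampled units."""
    s = np.asarray(s, dtype=np.intp).ravel()
    if s.size == 0:
        raise EstimationError("cannot predict a total from an empty sample")
    mask = np.ones(pop.N, dtype=bool)
    mask[s] = False
    s_bar = np.flatnonzero(mask)
    observed = _wy_sum(pop, s)
    predicted = float(_wx_sum(pop, s_bar) @ fit.b)
    return TotalEstimate(
        total=observed + predicted,
        components=(observed, predicted, 0.0, 0.0),
        method={"estimator": "full", "fit": fit.method, "v": fit.v},
    )


def predict_total_respondents_only(
    pop: FinitePopulation,
    draw: SampleDraw,
    fit1: LinearFit,
) -> TotalEstimate:
    """Respondent-only predictor: extrapolates the respondent-regime fit to
    every unobserved unit, including the whole non-respondent stratum.

    This is the biased comparison baseline; its model bias is
    W2' x2 (beta_r - beta_nr).
    """
    if draw.n1 == 0:
        raise EstimationError("no respondents in the sample")
    u2 = np.flatnonzero(draw.R == 0)
    observed = _wy_sum(pop, draw.s1)
    pred_resp = float(_wx_sum(pop, draw.s1_bar) @ fit1.b)
    pred_nonresp = float(_wx_sum(pop, u2) @ fit1.b)
    return TotalEstimate(
        total=observed + pred_resp + pred_nonresp,
        components=(observed, pred_resp, 0.0, pred_nonresp),
        method={"estimator": "respondents_only", "fit1": fit1.method,
                "v": fit1.v},
    )


def predict_total_subsampling(
    pop: FinitePopulation,
    draw: SampleDraw,
    fit1: LinearFit,
    fit2: Optional[LinearFit],
) -> TotalEstimate:
    """Sub-sampling predictor of the population total.

    total = sum_{s1} W y  +  sum_{U1 - s1} W x' b1
          + sum_{s'2} W y +  sum_{U2 - s'2} W x' b2

    ``fit1`` is trained on the first-call respondents, ``fit2`` on the
    second-call sub-sample; ``fit2`` may be an OLS, WLS or ridge fit (the
    latter giving the PRR variant).
    """
    if draw.n1 == 0:
        raise EstimationError("no respondents in the sample")
    if draw.n2 > 0 and draw.n2_prime == 0:
        raise EstimationError(
            "non-respondents present but the second-call sub-sample is empty"
        )
    observed1 = _wy_sum(pop, draw.s1)
    pred_resp = float(_wx_sum(pop, draw.s1_bar) @ fit1.b)
    observed2 = _wy_sum(pop, draw.s2_prime)
    if draw.s2_prime_bar.size == 0:
        pred_nonresp = 0.0
        fit2_method, fit2_v = None, 0.0
    else:
        if fit2 is None:
            raise EstimationError(
                "non-respondent units need prediction but fit2 is absent"
            )
        pred_nonresp = float(_wx_sum(pop, draw.s2_prime_bar) @ fit2.b)
        fit2_method, fit2_v = fit2.method, fit2.v
    return TotalEstimate(
        total=observed1 + pred_resp + observed2 + pred_nonresp,
        components=(observed1, pred_resp, observed2, pred_nonresp),
        method={"estimator": "subsampling", "fit1": fit1.method,
                "fit2": fit2_method, "v": fit2_v},
    )


@dataclass
class RidgePolicy:
    """How the non-respondent regime is fitted.

    mode "auto": OLS when n'2 > p+1, otherwise ridge with LOOCV-selected
    tuning; "force": always ridge; "never": always OLS (raises on
    super-collinearity).  ``v`` fixes the tuning parameter, bypassing
    selection; ``grid`` is the selection grid otherwise.
    """

    mode: str = "auto"
    v: Optional[float] = None
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_TUNING_GRID.copy())

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "force", "never"):
            raise InvalidSpecError("ridge policy mode must be auto/force/never")


def _fit_regime(
    X: np.ndarray,
    y: np.ndarray,
    policy: RidgePolicy,
    V: Optional[np.ndarray],
) -> LinearFit:
    n, q = X.shape
    use_ridge = policy.mode == "force" or (
        policy.mode == "auto" and n <= q
    )
    if not use_ridge and policy.mode == "auto":
        # n > p+1 does not guarantee a well-conditioned X'X; fall back to
        # ridge on numerical super-collinearity as well.
        try:
            return fit_wls(X, y, V) if V is not None else fit_ols(X, y)
        except SuperCollinearityError:
            use_ridge = True
    if use_ridge:
        if policy.v is not None:
            v = policy.v
        elif n < 2:
            # A single observation cannot be cross-validated; fall back to
            # the lightest penalty on the grid.
            v = float(np.min(policy.grid[policy.grid > 0]))
        else:
            v = select_tuning(X, y, policy.grid)
        return fit_prr(X, y, v)
    if V is not None:
        return fit_wls(X, y, V)
    return fit_ols(X, y)


def auto_fit_and_predict(
    pop: FinitePopulation,
    draw: SampleDraw,
    ridge_policy: Optional[RidgePolicy] = None,
    weight_structures: Optional[tuple[np.ndarray, np.ndarray]] = None,
    p_used: Optional[int] = None,
) -> TotalEstimate:
    """Fit both regimes with automatic ridge fallback and predict the total.

    The respondent regime is fitted by OLS (or WLS when per-unit variances
    are supplied in ``weight_structures = (V1 over U1, V2 over U2)`` as
    full-population vectors indexed like ``pop``).  The non-respondent
    regime is fitted on the second-call sub-sample, switching to ridge
    when the sub-sample cannot support OLS.  ``p_used`` restricts the fit
    and prediction to the first ``p_used`` covariates.

    The returned estimate's ``method`` records which fit each regime
    actually received, so any OLS-to-ridge fallback is auditable.
    """
    policy = ridge_policy or RidgePolicy()
    if draw.n1 == 0:
        raise EstimationError("no respondents in the sample")
    cols = slice(None) if p_used is None else slice(0, p_used + 1)
    Xv = pop.X[:, cols]
    V1 = V2 = None
    if weight_structures is not None:
        V1 = np.asarray(weight_structures[0], dtype=float)[draw.s1]
        V2full = np.asarray(weight_structures[1], dtype=float)
    # The respondent regime gets ridge only as a fallback (when n1 <= p+1);
    # "force" applies to the non-respondent regime, which is what makes the
    # estimator *partially* ridge.
    fit1_policy = RidgePolicy(mode="auto", v=policy.v, grid=policy.grid)
    fit1 = _fit_regime(Xv[draw.s1], pop.y[draw.s1], fit1_policy, V1)
    fit2 = None
    if draw.n2_prime > 0:
        if weight_structures is not None:
            V2 = V2full[draw.s2_prime]
        fit2 = _fit_regime(Xv[draw.s2_prime], pop.y[draw.s2_prime], policy, V2)
    pop_view = FinitePopulation(
        y=pop.y, X=Xv, R=pop.R, W=pop.W, metadata=pop.metadata
    ) if p_used is not None else pop
    est = predict_total_subsampling(pop_view, draw, fit1, fit2)
    est.method["p_used"] = Xv.shape[1] - 1
    return est
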