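"""Finite-population containers and synthetic-population generators.

The package treats a survey population of *N* units as a realisation of a
superpopulation model: an outcome vector ``y``, a design matrix ``X`` whose
first column is the intercept, a binary response-stratum indicator ``R``
(1 = respondent stratum, 0 = non-respondent stratum) and a prediction-weight
vector ``W`` (all ones for a total, all ``1/N`` for a mean).  Respondents and
non-respondents are allowed to follow *different* linear models

    Y_i = x_i' beta_r  + eps_1i   (R_i = 1),   Var(eps_1i) = sigma1^2
    Y_i = x_i' beta_nr + eps_2i   (R_i = 0),   Var(eps_2i) = sigma2^2

which is what makes the non-response non-ignorable: the respondent fit alone
is a biased predictor of the non-respondent stratum.

Two synthetic generators are provided.  ``make_two_regime_population`` draws
directly from the two-regime model above.  ``generate_simulation_population``
implements a single-model data-generating process where the response
stratum is carved out of the *outcome* distribution by quantile, so the
missingness depends on the unobserved outcome itself (NMAR) even though one
set of coefficients generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGammaError,
    InvalidSpecError,
    TieDegenerateError,
)

__all__ = [
    "FinitePopulation",
    "TwoRegimeModelSpec",
    "SimulationConfig",
    "make_two_regime_population",
    "generate_simulation_population",
    "assign_response_by_quantile",
    "load_population_csv",
    "emulate_blood_population",
]


@dataclass
class FinitePopulation:
    """A finite population with known covariates and prediction weights.

    Parameters
    ----------
    y : ndarray, shape (N,)
        Outcome values for every unit.
    X : ndarray, shape (N, p+1)
        Design matrix; column 0 must be the intercept (all ones).
    R : ndarray of {0,1} or None
        Response-stratum indicator; ``None`` if not yet assigned.
    W : ndarray, shape (N,)
        Prediction weights (ones for a total, 1/N for a mean).
    metadata : dict
        Generator-side truth (true coefficients, variances, total) used by
        the evaluation harnesses; empty for data loaded from file.
    """

    y: np.ndarray
    X: np.ndarray
    R: Optional[np.ndarray] = None
    W: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InvalidSpecError("X must be a 2-d design matrix")
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise InvalidSpecError(
                f"len(y)={n} but X has {self.X.shape[0]} rows"
            )
        if not np.allclose(self.X[:, 0], 1.0):
            raise InvalidSpecError("first column of X must be the intercept (all ones)")
        if self.W is None:
            self.W = np.ones(n)
        else:
            self.W = np.asarray(self.W, dtype=float).ravel()
            if self.W.shape[0] != n:
                raise InvalidSpecError("W must have one weight per unit")
        if self.R is not None:
            self.R = np.asarray(self.R)
            if self.R.shape[0] != n:
                raise InvalidSpecError("R must have one indicator per unit")
            if not np.isin(self.R, (0, 1)).all():
                raise InvalidSpecError("R must be binary")
            self.R = self.R.astype(np.int8)

    # -- basic geometry -------------------------------------------------
    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        """Number of covariates excluding the intercept."""
        return self.X.shape[1] - 1

    def _require_R(self) -> np.ndarray:
        if self.R is None:
            raise InvalidSpecError("response indicator R has not been assigned")
        return self.R

    @property
    def U1(self) -> np.ndarray:
        """Indices of the respondent stratum."""
        return np.flatnonzero(self._require_R() == 1)

    @property
    def U2(self) -> np.ndarray:
        """Indices of the non-respondent stratum."""
        return np.flatnonzero(self._require_R() == 0)

    @property
    def N1(self) -> int:
        return int(self._require_R().sum())

    @property
    def N2(self) -> int:
        return self.N - self.N1

    @property
    def lambda1(self) -> float:
        return self.N1 / self.N

    @property
    def lambda2(self) -> float:
        return self.N2 / self.N

    @property
    def total(self) -> float:
        """The weighted population total W'y (the estimand)."""
        return float(self.W @ self.y)

    def with_response(self, R: np.ndarray) -> "FinitePopulation":
        """Return a copy of this population with response indicator ``R``."""
        return FinitePopulation(
            y=self.y.copy(), X=self.X.copy(), R=np.asarray(R).copy(),
            W=self.W.copy(), metadata=dict(self.metadata),
        )


VarianceStructure = Callable[[np.ndarray], np.ndarray]
CovariateLaw = Callable[[np.random.Generator, int], np.ndarray]


@dataclass
class TwoRegimeModelSpec:
    """Superpopulation model with separate respondent / non-respondent regimes.

    ``beta_r`` and ``beta_nr`` include the intercept coefficient in position
    0.  ``var_structure_*``, when given, map the covariate block (without
    intercept) of a regime to strictly positive per-unit error variances,
    scaled by the corresponding ``sigma*_sq``; when absent the errors are
    homoscedastic.  ``covariate_law`` maps ``(rng, n)`` to an ``n x p``
    covariate block; the default is standard normal.
    """

    beta_r: np.ndarray
    beta_nr: np.ndarray
    sigma1_sq: float = 1.0
    sigma2_sq: float = 1.0
    var_structure_r: Optional[VarianceStructure] = None
    var_structure_nr: Optional[VarianceStructure] = None
    covariate_law: Optional[CovariateLaw] = None

    def __post_init__(self) -> None:
        self.beta_r = np.asarray(self.beta_r, dtype=float).ravel()
        self.beta_nr = np.asarray(self.beta_nr, dtype=float).ravel()
        if self.beta_r.shape != self.beta_nr.shape:
            raise InvalidSpecError("beta_r and beta_nr must have equal length")
        if self.sigma1_sq < 0 or self.sigma2_sq < 0:
            raise InvalidSpecError("error variances must be nonnegative")

    @property
    def p(self) -> int:
        return self.beta_r.shape[0] - 1


def _unit_sds(
    sigma_sq: float,
    structure: Optional[VarianceStructure],
    Z: np.ndarray,
) -> np.ndarray:
    if structure is None:
        v = np.full(Z.shape[0], sigma_sq)
    else:
        v = sigma_sq * np.asarray(structure(Z), dtype=float).ravel()
        if Z.shape[0] and (v <= 0).any() and sigma_sq > 0:
            raise InvalidSpecError("variance structure must be strictly positive")
    return np.sqrt(v)


def make_two_regime_population(
    spec: TwoRegimeModelSpec,
    N1: int,
    N2: int,
    seed: int | np.random.Generator = 0,
) -> FinitePopulation:
    """Draw a finite population from the two-regime linear model.

    The first ``N1`` units form the respondent stratum (R=1) with outcome
    ``x'beta_r + eps1``; the remaining ``N2`` form the non-respondent
    stratum (R=0) with outcome ``x'beta_nr + eps2``.  Errors are independent
    with mean zero and regime-specific variances.  The true coefficients,
    variances and total are recorded in ``metadata['truth']`` so the
    Monte-Carlo auditors can redraw errors from the same law.
    """
    if N1 + N2 == 0:
        raise InvalidSpecError("population must contain at least one unit")
    if N1 < 0 or N2 < 0:
        raise InvalidSpecError("stratum sizes must be nonnegative")
    rng = np.random.default_rng(seed)
    N = N1 + N2
    p = spec.p
    law = spec.covariate_law or (lambda g, n: g.standard_normal((n, p)))
    Z = np.asarray(law(rng, N), dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape != (N, p):
        raise InvalidSpecError(
            f"covariate law returned shape {Z.shape}, expected {(N, p)}"
        )
    X = np.column_stack([np.ones(N), Z])
    R = np.zeros(N, dtype=np.int8)
    R[:N1] = 1
    sd = np.empty(N)
    sd[:N1] = _unit_sds(spec.sigma1_sq, spec.var_structure_r, Z[:N1])
    sd[N1:] = _unit_sds(spec.sigma2_sq, spec.var_structure_nr, Z[N1:])
    mean = np.empty(N)
    mean[:N1] = X[:N1] @ spec.beta_r
    mean[N1:] = X[N1:] @ spec.beta_nr
    y = mean + sd * rng.standard_normal(N)
    pop = FinitePopulation(
        y=y, X=X, R=R, W=np.ones(N),
        metadata={
            "truth": {
                "kind": "two_regime",
                "beta_r": spec.beta_r.copy(),
                "beta_nr": spec.beta_nr.copy(),
                "sigma1_sq": spec.sigma1_sq,
                "sigma2_sq": spec.sigma2_sq,
                "unit_sd": sd,
                "mean": mean,
            },
        },
    )
    pop.metadata["true_total"] = pop.total
    return pop


@dataclass
class SimulationConfig:
    """Configuration of one cell of the nested simulation study.

    ``N`` population size, ``n`` first-call sample size, ``p`` covariates,
    ``k`` sub-sampling divisor (sub-sample size is n2/k), ``lambda2``
    population non-response rate, ``rho`` covariate-dependence parameter of
    the DGP, ``sigma_sq`` model error variance.  ``reps_outer`` fresh
    sample draws; ``reps_inner`` sub-sample redraws averaged within each
    outer draw.  ``dgp_variant`` selects how the covariate matrix is built
    from the latent normal draws (see ``generate_simulation_population``),
    and ``response_tail`` selects which tail of the outcome distribution is
    the respondent stratum.
    """

    N: int = 10_000
    n: int = 100
    p: int = 8
    k: float = 2.0
    lambda2: float = 0.2
    rho: float = 0.5
    sigma_sq: float = 0.01
    reps_outer: int = 2000
    reps_inner: int = 500
    seed: int = 0
    dgp_variant: str = "literal"
    response_tail: str = "lower"

    def __post_init__(self) -> None:
        if self.N <= 0 or self.n <= 0 or self.n > self.N:
            raise InvalidSpecError("need 0 < n <= N")
        if self.p < 1:
            raise InvalidSpecError("simulation DGP needs at least one covariate")
        if self.k < 1:
            raise InvalidSpecError("sub-sampling divisor k must be >= 1")
        if not 0 <= self.lambda2 < 1:
            raise InvalidSpecError("lambda2 must lie in [0, 1)")
        if self.sigma_sq < 0:
            raise InvalidSpecError("sigma_sq must be nonnegative")
        if self.reps_outer < 1 or self.reps_inner < 1:
            raise InvalidSpecError("replication counts must be >= 1")
        if self.dgp_variant not in ("literal", "latent"):
            raise InvalidSpecError("dgp_variant must be 'literal' or 'latent'")
        if self.response_tail not in ("upper", "lower"):
            raise InvalidSpecError("response_tail must be 'upper' or 'lower'")


def assign_response_by_quantile(
    y: np.ndarray,
    lambda2: float,
    tail: str = "upper",
) -> np.ndarray:
    """Stratify a population into respondents / non-respondents by outcome.

    A fraction ``1 - lambda2`` of the units is marked as the respondent
    stratum (R=1).  ``tail="upper"`` marks the units with the *largest*
    outcomes as respondents; ``tail="lower"`` the smallest.  Units whose
    outcome falls exactly on the threshold value are assigned to the
    respondent stratum.  This is the NMAR mechanism: stratum membership is
    a deterministic function of the outcome itself.

    Raises
    ------
    TieDegenerateError
        If ties at the threshold are so heavy the requested split is
        impossible (e.g. all outcomes equal while 0 < lambda2 < 1).
    """
    y = np.asarray(y, dtype=float).ravel()
    if not 0 <= lambda2 < 1:
        raise InvalidSpecError("lambda2 must lie in [0, 1)")
    if tail not in ("upper", "lower"):
        raise InvalidSpecError("tail must be 'upper' or 'lower'")
    N = y.shape[0]
    if N == 0:
        raise InvalidSpecError("cannot stratify an empty outcome vector")
    if lambda2 == 0:
        return np.ones(N, dtype=np.int8)
    n_resp = int(np.ceil((1.0 - lambda2) * N))
    order = np.sort(y)
    if tail == "upper":
        threshold = order[N - n_resp]
        R = (y >= threshold).astype(np.int8)
    else:
        threshold = order[n_resp - 1]
        R = (y <= threshold).astype(np.int8)
    # n_resp == N can happen legitimately through ceil-rounding at small
    # lambda2*N; degeneracy is ties inflating the marked count to all of U.
    if int(R.sum()) == N and n_resp < N:
        raise TieDegenerateError(
            "outcome ties at the threshold prevent a "
            f"{1 - lambda2:.0%}/{lambda2:.0%} respondent/non-respondent split"
        )
    return R


def _simulation_gamma(Z: np.ndarray) -> np.ndarray:
    """Coefficient vector for the simulation DGP.

    Eigendecompose H = x'x on the covariate block, keep the unit-norm
    eigenvectors whose eigenvalues exceed one, flip each eigenvector's sign
    so its largest-magnitude entry is positive, and average element-wise.
    The sign normalisation removes the arbitrary orientation of
    eigenvectors, which would otherwise make the coefficient vector
    ill-defined.
    """
    H = Z.T @ Z
    eigval, eigvec = np.linalg.eigh(H)
    keep = eigval > 1.0
    if not keep.any():
        raise DegenerateGammaError(
            "no eigenvalue of x'x exceeds 1; the simulation coefficient "
            "vector is undefined for this covariate draw"
        )
    vecs = eigvec[:, keep]
    signs = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return (vecs * signs).mean(axis=1)


def generate_simulation_population(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> FinitePopulation:
    """Generate the simulation-study population.

    A latent matrix ``z`` of shape N x p is drawn i.i.d. N(100, 1).  The
    covariate matrix is either a literal blend of each column with itself,

        x_ij = (1-rho)^0.5 * z_ij + rho * z_ij        (variant "literal")

    which rescales every column by the same factor, or a shared-factor
    construction that induces genuine cross-column correlation,

        x_ij = (1-rho^2)^0.5 * z_ij + rho * z_i,p+1   (variant "latent")

    with one extra latent column common to all covariates.  The outcome is
    ``y = x gamma + eps`` with ``eps ~ N(0, sigma^2 I)`` and ``gamma`` the
    averaged sign-normalised unit eigenvectors of ``x'x`` with eigenvalue
    above one.  The response stratum is then assigned by outcome quantile
    at rate ``1 - lambda2`` on the configured tail, so the missingness is
    non-ignorable by construction.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N, p, rho = config.N, config.p, config.rho
    Z = rng.normal(100.0, 1.0, size=(N, p))
    if config.dgp_variant == "literal":
        Zx = (np.sqrt(1.0 - rho) + rho) * Z
    else:
        shared = rng.normal(100.0, 1.0, size=N)
        Zx = np.sqrt(1.0 - rho**2) * Z + rho * shared[:, None]
    gamma = _simulation_gamma(Zx)
    mean = Zx @ gamma
    y = mean + np.sqrt(config.sigma_sq) * rng.standard_normal(N)
    R = assign_response_by_quantile(y, config.lambda2, config.response_tail)
    X = np.column_stack([np.ones(N), Zx])
    beta = np.concatenate([[0.0], gamma])
    pop = FinitePopulation(
        y=y, X=X, R=R, W=np.ones(N),
        metadata={
            "gamma": gamma,
            "rho": rho,
            "dgp_variant": config.dgp_variant,
            "truth": {
                "kind": "single",
                "beta": beta,
                "sigma_sq": config.sigma_sq,
                "unit_sd": np.full(N, np.sqrt(config.sigma_sq)),
                "mean": mean,
            },
        },
    )
    pop.metadata["true_total"] = pop.total
    return pop


def load_population_csv(
    path,
    outcome_col: str,
    covariate_cols: list[str],
    weight_mode: str = "total",
) -> FinitePopulation:
    """Read a population table from CSV.

    An intercept column is prepended to the named covariates.  The response
    indicator is left unassigned; use :func:`assign_response_by_quantile`
    or supply one later.  ``weight_mode`` "total" gives unit weights,
    "mean" gives 1/N.
    """
    if weight_mode not in ("total", "mean"):
        raise InvalidSpecError("weight_mode must be 'total' or 'mean'")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InvalidSpecError(f"population file {path!r} is empty") from exc
    missing = [c for c in [outcome_col, *covariate_cols] if c not in df.columns]
    if missing:
        raise InvalidSpecError(
            f"columns {missing} not found in {path!r}; "
            f"available: {list(df.columns)}"
        )
    used = df[[outcome_col, *covariate_cols]]
    numeric = used.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().any()
        raise InvalidSpecError(
            f"non-numeric or missing values in columns "
            f"{list(bad.index[bad])} of {path!r}"
        )
    N = len(numeric)
    if N == 0:
        raise InvalidSpecError(f"population file {path!r} has no data rows")
    y = numeric[outcome_col].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(N)] + [numeric[c].to_numpy(dtype=float) for c in covariate_cols]
    )
    W = np.ones(N) if weight_mode == "total" else np.full(N, 1.0 / N)
    return FinitePopulation(y=y, X=X, R=None, W=W,
                            metadata={"source": str(path)})


# Size and column layout of the blood-donor application table.
_BLOOD_N = 748
_BLOOD_COLUMNS = ("time", "recency", "frequency")


def emulate_blood_population(seed: int | np.random.Generator = 0) -> FinitePopulation:
    """Synthetic stand-in for the 748-donor blood-transfusion table.

    Generates 748 donors with months since first donation ("time"), months
    since last donation ("recency"), number of donations ("frequency") and
    the outcome, total blood donated in c.c. ("monetary", a fixed 250 c.c.
    per donation).  The generator is calibrated to the published marginal
    moments of the real donor registry (time mean ~34, sd ~24; recency
    mean ~9.5, sd ~8; frequency mean ~5.5, sd ~5.8, heavily right-skewed)
    and to its dependence structure: the outcome is exactly proportional
    to frequency, strongly associated with time and only weakly with
    recency.  It is a synthetic fixture for offline use; conclusions about
    the real registry require the real table via ``load_population_csv``.

    The design matrix columns are (intercept, time, recency, frequency),
    matching the application's covariate ordering, so "first two
    covariates" selects time and recency.
    """
    rng = np.random.default_rng(seed)
    N = _BLOOD_N
    # Donor tenure in months: 2 + gamma, capped at 98.
    time = 2.0 + np.round(rng.gamma(1.8, 18.0, size=N))
    time = np.minimum(time, 98.0)
    # Donation count: 1 + overdispersed Poisson with rate growing in tenure.
    mu = 0.135 * time
    lam = mu * rng.gamma(1.65, 1.0 / 1.65, size=N)
    freq = 1.0 + rng.poisson(lam)
    freq = np.minimum(freq, 50.0)
    # Months since last donation: frequent donors donated more recently,
    # but only mildly so.
    rec_mean = 11.5 / (0.9 + 0.06 * freq)
    recency = np.round(rng.gamma(1.5, rec_mean / 1.5, size=N))
    recency = np.clip(recency, 0.0, 74.0)
    monetary = 250.0 * freq
    X = np.column_stack([np.ones(N), time, recency, freq])
    return FinitePopulation(
        y=monetary, X=X, R=None, W=np.ones(N),
        metadata={"source": "synthetic blood-donor emulator",
                  "columns": _BLOOD_COLUMNS},
    )
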