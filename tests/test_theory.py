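import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbtotal import (
    FinitePopulation,
    InvalidSpecError,
    SampleDraw,
    SimulationConfig,
    TwoRegimeModelSpec,
    bias_respondents_only,
    empirical_prediction_moments,
    expected_var_full,
    expected_var_subsampling,
    fit_ols,
    make_two_regime_population,
    mse_respondents_only,
    predict_total_respondents_only,
    predict_total_subsampling,
    var_subsampling,
)


class TestBiasRespondentsOnly:
    def test_equal_coefficients_and_empty_stratum(self):
        X2 = np.column_stack([np.ones(4), np.arange(4.0)])
        assert bias_respondents_only(np.ones(4), X2, [1.0, 2.0], [1.0, 2.0]) == 0.0
        assert bias_respondents_only(np.ones(0), np.empty((0, 2)),
                                     [1.0, 2.0], [0.0, 1.0]) == 0.0

    def test_hand_computed_matrix_product(self):
        X2 = np.array([[1.0, 1], [1, 2], [1, 3], [1, 4]])
        gap = np.array([-10.0, 0.0])
        b = bias_respondents_only(np.ones(4), X2, gap, np.zeros(2))
        assert b == pytest.approx(-40.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(-5.0, 5.0))
    def test_linear_in_coefficient_gap(self, scale):
        rng = np.random.default_rng(17)
        X2 = np.column_stack([np.ones(6), rng.standard_normal((6, 2))])
        W2 = rng.uniform(0.5, 2.0, 6)
        gap = np.array([1.0, -2.0, 0.5])
        base = bias_respondents_only(W2, X2, gap, np.zeros(3))
        scaled = bias_respondents_only(W2, X2, scale * gap, np.zeros(3))
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-9)


def brute_force_mse_resp_only(pop, draw, s1sq, s2sq, beta1, beta2):
    """Second, independent implementation of the closed-form decomposition."""
    Hinv = np.linalg.inv(pop.X[draw.s1].T @ pop.X[draw.s1])
    a1 = pop.X[draw.s1_bar].T @ pop.W[draw.s1_bar]
    u2 = np.flatnonzero(draw.R == 0)
    a2 = pop.X[u2].T @ pop.W[u2]
    var = s1sq * (draw.n1 + a1 @ Hinv @ a1) + s2sq * (a2 @ Hinv @ a2)
    bias = float(pop.W[u2] @ (pop.X[u2] @ (np.asarray(beta1) - np.asarray(beta2))))
    return bias, var


def brute_force_var_sub(pop, draw, s1sq, s2sq):
    H1inv = np.linalg.inv(pop.X[draw.s1].T @ pop.X[draw.s1])
    a1 = pop.X[draw.s1_bar].T @ pop.W[draw.s1_bar]
    H2inv = np.linalg.inv(pop.X[draw.s2_prime].T @ pop.X[draw.s2_prime])
    a2 = pop.X[draw.s2_prime_bar].T @ pop.W[draw.s2_prime_bar]
    return (s1sq * draw.n1 + s2sq * draw.n2_prime
            + s1sq * a1 @ H1inv @ a1 + s2sq * a2 @ H2inv @ a2)


class TestClosedFormsAgainstBruteForce:
    def test_mse_respondents_only_matches_oracle(self, toy_two_regime_pop, toy_draw):
        pop, d = toy_two_regime_pop, toy_draw
        beta1, beta2 = [1.0, 2.0, -1.0], [4.0, 0.5, 1.5]
        dec = mse_respondents_only(d, pop, 1.0, 2.0, beta1, beta2)
        bias, var = brute_force_mse_resp_only(pop, d, 1.0, 2.0, beta1, beta2)
        assert dec.bias_m == pytest.approx(bias, rel=1e-9)
        assert dec.var_m == pytest.approx(var, rel=1e-9)
        assert dec.mse_m == pytest.approx(bias**2 + var, rel=1e-9)

    def test_var_subsampling_matches_oracle(self, toy_two_regime_pop, toy_draw):
        pop, d = toy_two_regime_pop, toy_draw
        v = var_subsampling(d, pop, 1.0, 2.0)
        assert v == pytest.approx(brute_force_var_sub(pop, d, 1.0, 2.0), rel=1e-9)

    def test_noise_free_everything_zero(self, toy_two_regime_pop, toy_draw):
        pop, d = toy_two_regime_pop, toy_draw
        beta = [1.0, 2.0, -1.0]
        dec = mse_respondents_only(d, pop, 0.0, 0.0, beta, beta)
        assert dec.bias_m == 0.0 and dec.var_m == 0.0 and dec.mse_m == 0.0
        assert var_subsampling(d, pop, 0.0, 0.0) == 0.0

    def test_homogeneous_model_closed_scalar_forms(self):
        # p = 0, W = 1: the quadratic forms collapse to (N1-n1)^2/n1,
        # N2^2/n1 (respondent-only) and (N2-n'2)^2/n'2 (sub-sampling)
        N, N1 = 20, 12
        R = (np.arange(N) < N1).astype(int)
        pop = FinitePopulation(y=np.arange(N, dtype=float), X=np.ones((N, 1)), R=R)
        d = SampleDraw(N=N, R=R, s=np.r_[0:5, 12:16], s1=np.r_[0:5],
                       s2=np.r_[12:16], s2_prime=np.r_[12:14], k=2)
        n1, n2p, N2 = 5, 2, 8
        s1sq, s2sq = 1.5, 2.5
        dec = mse_respondents_only(d, pop, s1sq, s2sq, [0.0], [0.0])
        expected_var = s1sq * (n1 + (N1 - n1) ** 2 / n1) + s2sq * N2**2 / n1
        assert dec.var_m == pytest.approx(expected_var, rel=1e-12)
        v = var_subsampling(d, pop, s1sq, s2sq)
        expected_v = (s1sq * n1 + s2sq * n2p
                      + s1sq * (N1 - n1) ** 2 / n1 + s2sq * (N2 - n2p) ** 2 / n2p)
        assert v == pytest.approx(expected_v, rel=1e-12)

    def test_variance_monotone_in_sigmas(self, toy_two_regime_pop, toy_draw):
        pop, d = toy_two_regime_pop, toy_draw
        v00 = var_subsampling(d, pop, 1.0, 1.0)
        assert var_subsampling(d, pop, 2.0, 1.0) > v00
        assert var_subsampling(d, pop, 1.0, 2.0) > v00
        assert v00 >= 0


class TestExpectedVariance:
    def test_noise_free_zero(self, toy_two_regime_pop):
        cfg = SimulationConfig(N=30, n=16, p=2, k=2.0, lambda2=0.4, seed=0,
                               reps_outer=5, reps_inner=5)
        assert expected_var_subsampling(toy_two_regime_pop, cfg, 0.0, 0.0,
                                        reps=20, seed=0) == 0.0

    def test_census_design_keeps_leading_terms_only(self, toy_two_regime_pop):
        pop = toy_two_regime_pop
        cfg = SimulationConfig(N=pop.N, n=pop.N, p=2, k=1.0, lambda2=0.4,
                               seed=0, reps_outer=5, reps_inner=5)
        v = expected_var_subsampling(pop, cfg, 1.0, 2.0, reps=10, seed=1)
        assert v == pytest.approx(pop.N1 * 1.0 + pop.N2 * 2.0)

    def test_reproducible_and_converging(self):
        spec = TwoRegimeModelSpec(beta_r=[1.0, 2.0, -1.0],
                                  beta_nr=[4.0, 0.5, 1.5])
        pop = make_two_regime_population(spec, N1=120, N2=80, seed=7)
        cfg = SimulationConfig(N=pop.N, n=60, p=2, k=2.0, lambda2=0.4,
                               seed=0, reps_outer=5, reps_inner=5)
        a = expected_var_subsampling(pop, cfg, 1.0, 1.0, reps=300, seed=5)
        b = expected_var_subsampling(pop, cfg, 1.0, 1.0, reps=300, seed=5)
        assert a == b
        c = expected_var_subsampling(pop, cfg, 1.0, 1.0, reps=600, seed=6)
        assert c == pytest.approx(a, rel=0.25)

    def test_full_response_analogue_runs(self, toy_two_regime_pop):
        v = expected_var_full(toy_two_regime_pop, n=20, sigma_sq=1.0,
                              reps=50, seed=2)
        assert v > 0


def _sub_fitter(pop, draw):
    fit1 = fit_ols(pop.X[draw.s1], pop.y[draw.s1])
    fit2 = fit_ols(pop.X[draw.s2_prime], pop.y[draw.s2_prime])
    return predict_total_subsampling(pop, draw, fit1, fit2)


def _resp_fitter(pop, draw):
    fit1 = fit_ols(pop.X[draw.s1], pop.y[draw.s1])
    return predict_total_respondents_only(pop, draw, fit1)


@pytest.fixture(scope="module")
def audit_setup():
    spec = TwoRegimeModelSpec(beta_r=[1.0, 2.0], beta_nr=[6.0, -1.0],
                              sigma1_sq=1.0, sigma2_sq=1.0)
    pop = make_two_regime_population(spec, N1=120, N2=80, seed=31)
    s1 = pop.U1[:30]
    s2 = pop.U2[:20]
    d = SampleDraw(N=pop.N, R=pop.R, s=np.concatenate([s1, s2]), s1=s1,
                   s2=s2, s2_prime=s2[:10], k=2)
    return pop, d


class TestEmpiricalPredictionMoments:
    def test_noise_free_population_has_no_error(self):
        spec = TwoRegimeModelSpec(beta_r=[1.0, 2.0], beta_nr=[6.0, -1.0],
                                  sigma1_sq=0.0, sigma2_sq=0.0)
        pop = make_two_regime_population(spec, N1=40, N2=20, seed=3)
        s1, s2 = pop.U1[:10], pop.U2[:8]
        d = SampleDraw(N=pop.N, R=pop.R, s=np.concatenate([s1, s2]), s1=s1,
                       s2=s2, s2_prime=s2[:4], k=2)
        dec = empirical_prediction_moments(pop, d, _sub_fitter,
                                           error_reps=50, seed=0)
        assert dec.bias_m == pytest.approx(0.0, abs=1e-8)
        assert dec.var_m == pytest.approx(0.0, abs=1e-12)

    def test_subsampling_estimator_unbiased(self, audit_setup):
        pop, d = audit_setup
        dec = empirical_prediction_moments(pop, d, _sub_fitter,
                                           error_reps=2000, seed=41)
        assert abs(dec.bias_m) <= 3 * dec.bias_se

    def test_respondent_only_bias_matches_closed_form(self, audit_setup):
        pop, d = audit_setup
        dec = empirical_prediction_moments(pop, d, _resp_fitter,
                                           error_reps=2000, seed=42)
        u2 = pop.U2
        expected = bias_respondents_only(pop.W[u2], pop.X[u2],
                                         [1.0, 2.0], [6.0, -1.0])
        assert dec.bias_m == pytest.approx(expected, abs=3 * dec.bias_se)

    def test_requires_generating_truth(self, audit_setup):
        pop, d = audit_setup
        bare = FinitePopulation(y=pop.y, X=pop.X, R=pop.R)
        with pytest.raises(InvalidSpecError):
            empirical_prediction_moments(bare, d, _sub_fitter, 10, 0)
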