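import numpy as np
import pytest

from mbtotal import (
    SampleDraw,
    TwoRegimeModelSpec,
    make_two_regime_population,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_two_regime_pop():
    """Small noisy two-regime population with known truth (N=30, p=2)."""
    spec = TwoRegimeModelSpec(
        beta_r=[1.0, 2.0, -1.0],
        beta_nr=[4.0, 0.5, 1.5],
        sigma1_sq=1.0,
        sigma2_sq=2.0,
    )
    return make_two_regime_population(spec, N1=18, N2=12, seed=7)


@pytest.fixture
def toy_draw(toy_two_regime_pop):
    """A fixed draw on the toy population with both regimes represented."""
    pop = toy_two_regime_pop
    rng = np.random.default_rng(99)
    s = rng.choice(pop.N, size=16, replace=False)
    s1 = s[pop.R[s] == 1]
    s2 = s[pop.R[s] == 0]
    s2p = rng.choice(s2, size=max(4, s2.size // 2), replace=False)
    return SampleDraw(N=pop.N, R=pop.R, s=s, s1=s1, s2=s2, s2_prime=s2p, k=2.0)


def brute_force_quad(a, H):
    """Independent quadratic-form evaluation a' H^{-1} a via explicit inverse."""
    return float(a @ np.linalg.inv(H) @ a)
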