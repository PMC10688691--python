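import numpy as np
import pytest
from scipy.stats import gamma

from ipdssr import (
    MCMCConfig,
    PriorSpec,
    bayes_ssr,
    hpd_interval,
    log_conditional,
    mh_sample,
)
from conftest import complete_sample


@pytest.fixture(scope="module")
def small_chain(jute):
    cfg = MCMCConfig(n_draws=4000, burn_in=1000, seed=123)
    return mh_sample(jute.x_pffc[1], jute.y_pffc[1], PriorSpec(), cfg)


def test_chain_deterministic_under_seed(jute):
    cfg = MCMCConfig(n_draws=500, burn_in=100, seed=7)
    c1 = mh_sample(jute.x_pffc[1], jute.y_pffc[1], PriorSpec(), cfg)
    c2 = mh_sample(jute.x_pffc[1], jute.y_pffc[1], PriorSpec(), cfg)
    np.testing.assert_array_equal(c1.phi, c2.phi)


def test_phi_chain_is_deterministic_image(small_chain):
    np.testing.assert_allclose(
        small_chain.phi,
        small_chain.alpha1 / (small_chain.alpha1 + small_chain.alpha2),
        rtol=1e-14,
    )
    assert np.all(small_chain.alpha1 > 0) and np.all(small_chain.alpha2 > 0)


def test_conditional_is_gamma_kernel_without_censoring():
    # k=1, G=0: the conditional must equal a Gamma(m+r, s-S) log-kernel
    sample = complete_sample([0.5, 1.0, 2.0, 4.0])
    r, s = 2.0, 1.5
    S = np.sum(np.log(sample.times / (1 + sample.times)))
    shape, rate = sample.m + r, s - S
    for a in [0.3, 1.0, 2.7]:
        expected = (shape - 1) * np.log(a) - rate * a
        assert log_conditional(a, sample, r, s) == pytest.approx(expected, abs=1e-10)


def test_conditional_derivative_matches_finite_difference(insulation):
    sample = insulation.x_pffc[1]
    r, s = 0.5, 0.5
    a = 1.2
    eps = 1e-6
    fd = (log_conditional(a + eps, sample, r, s)
          - log_conditional(a - eps, sample, r, s)) / (2 * eps)
    lu = np.log(sample.times / (1 + sample.times))
    ua = np.exp(a * lu)
    analytic = (sample.m + r - 1) / a - (s - lu.sum()) - np.sum(
        sample.censor_coefficients * ua * lu / (1 - ua)
    )
    assert fd == pytest.approx(analytic, rel=1e-6)


def test_mh_recovers_conjugate_gamma_posterior(jute):
    # complete-sample case: the exact posterior is Gamma(m+r, s-S), so the
    # chain mean and quantiles must match the closed form within MC error
    sample = complete_sample(jute.x_full)
    r = s = 1e-4
    S = np.sum(np.log(sample.times / (1 + sample.times)))
    shape, rate = sample.m + r, s - S
    cfg = MCMCConfig(n_draws=20_000, burn_in=4_000, seed=2024)
    chain = mh_sample(sample, sample, PriorSpec(r, s, r, s), cfg)
    draws = chain.post_burn_in("alpha1")
    exact_mean = shape / rate
    exact_sd = np.sqrt(shape) / rate
    ess_floor = len(draws) / 30  # generous autocorrelation allowance
    mc_se = exact_sd / np.sqrt(ess_floor)
    assert abs(draws.mean() - exact_mean) < 3 * mc_se
    for q in (0.1, 0.5, 0.9):
        assert abs(np.quantile(draws, q) - gamma.ppf(q, shape, scale=1 / rate)) < 4 * mc_se


def test_posterior_follows_overwhelming_prior(jute):
    # prior Gamma(c*s, s) with huge s pins the posterior at the prior mean c
    c, s = 3.0, 1e6
    prior = PriorSpec(r1=c * s, s1=s, r2=c * s, s2=s)
    cfg = MCMCConfig(n_draws=6000, burn_in=2000, seed=5,
                     proposal_scale1=0.005, proposal_scale2=0.005, init=(c, c))
    chain = mh_sample(jute.x_pffc[1], jute.y_pffc[1], prior, cfg)
    assert chain.post_burn_in("alpha1").mean() == pytest.approx(c, rel=0.01)


def test_bayes_ssr_uses_post_burn_in_draws_only(small_chain):
    est = bayes_ssr(small_chain)
    kept = small_chain.phi[small_chain.burn_in:]
    assert est.phi == pytest.approx(kept.mean(), abs=1e-15)
    # perturbing only burn-in draws must leave the estimate unchanged
    mangled = small_chain.phi.copy()
    mangled[: small_chain.burn_in] = 0.123
    assert mangled[small_chain.burn_in:].mean() == pytest.approx(est.phi, abs=1e-15)


class TestHPD:
    def test_integer_ladder_tie_broken_at_smallest_start(self):
        draws = np.arange(1, 101, dtype=float)
        assert hpd_interval(draws, 0.95) == (1.0, 96.0)

    def test_constant_draws(self):
        lo, hi = hpd_interval(np.full(50, 0.4), 0.95)
        assert (lo, hi) == (0.4, 0.4)

    def test_never_wider_than_equal_tail(self):
        rng = np.random.default_rng(3)
        for draws in (rng.normal(size=2000), rng.gamma(2.0, size=2000),
                      rng.beta(0.5, 3.0, size=2000)):
            lo, hi = hpd_interval(draws, 0.95)
            eq = np.quantile(draws, [0.025, 0.975])
            assert hi - lo <= eq[1] - eq[0] + 1e-12

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        draws = rng.gamma(3.0, size=999)
        lo, hi = hpd_interval(draws, 0.9)
        srt = np.sort(draws)
        width = int(np.floor(0.9 * len(srt)))
        widths = [(srt[t + width] - srt[t], srt[t], srt[t + width])
                  for t in range(len(srt) - width)]
        best = min(widths, key=lambda w: w[0])
        assert (lo, hi) == (best[1], best[2])

    @pytest.mark.parametrize("bad_level", [0.0, 1.0, -0.2, 1.7])
    def test_level_domain(self, bad_level):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(100.0), bad_level)

    def test_minimum_draw_count(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(5.0), 0.9)
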