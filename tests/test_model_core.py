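"""Mixture pmf, moments, eta and likelihood of the marginalized model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ancmix.model_core import (
    PENALTY_BASE,
    DesignData,
    MarginalizedParams,
    eta,
    marginal_moments,
    marginalized_loglik,
    mixture_log_pmf,
    mu2_from_marginal,
)
from ancmix.synthetic_data import simulate_counts


def brute_force_moments(mu1, mu2, pi, ymax=300):
    """pmf-summation oracle for the marginal mean and variance."""
    ys = np.arange(ymax + 1)
    pmf = np.exp(mixture_log_pmf(ys, mu1, mu2, pi))
    mean = float(np.sum(ys * pmf))
    var = float(np.sum(ys**2 * pmf) - mean**2)
    return mean, var


class TestMixtureLogPmf:
    @pytest.mark.parametrize(
        "y, mu1, mu2, pi, expected",
        [
            (0, 1.0, 1.0, 0.5, -1.0),  # mixture of identical Poisson(1)
            (0, 2.0, 1.0, 1.0, -2.0),  # pure first component
        ],
    )
    def test_hand_values(self, y, mu1, mu2, pi, expected):
        assert mixture_log_pmf(y, mu1, mu2, pi) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("mu1, mu2, pi", [(1, 5, 0.3), (2, 7, 0.5), (0.5, 10, 0.9)])
    def test_normalization(self, mu1, mu2, pi):
        ys = np.arange(201)
        total = np.sum(np.exp(mixture_log_pmf(ys, mu1, mu2, pi)))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_large_counts_no_overflow(self):
        val = mixture_log_pmf(1000, 1000.0, 500.0, 0.4)
        assert np.isfinite(val)

    def test_rejects_negative_or_fractional_counts(self):
        with pytest.raises(ValueError):
            mixture_log_pmf(-1, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            mixture_log_pmf(1.5, 1.0, 1.0, 0.5)


class TestMu2FromMarginal:
    def test_formula_and_round_trip(self):
        mu2 = mu2_from_marginal(2.0, 1.0, 0.5)
        assert mu2 == pytest.approx(3.0)
        assert 0.5 * 1.0 + 0.5 * mu2 == pytest.approx(2.0, abs=1e-14)

    def test_near_zero_pi_limit(self):
        assert mu2_from_marginal(2.0, 1.0, 1e-12) == pytest.approx(2.0, rel=1e-9)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            mu2_from_marginal(1.0, 4.0, 0.5)

    @given(
        mu=st.floats(0.5, 20),
        mu1_frac=st.floats(0.05, 0.95),
        pi=st.floats(0.05, 0.95),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_property(self, mu, mu1_frac, pi):
        mu1 = mu1_frac * mu / pi  # keeps pi*mu1 < mu, hence mu2 > 0
        mu2 = mu2_from_marginal(mu, mu1, pi)
        assert pi * mu1 + (1 - pi) * mu2 == pytest.approx(mu, rel=1e-10)


class TestMarginalMoments:
    def test_equal_components_reduce_to_poisson(self):
        for pi in (0.0, 0.3, 1.0):
            m = marginal_moments(3.0, 3.0, pi)
            assert m.mu == pytest.approx(3.0)
            assert m.var == pytest.approx(3.0)

    def test_hand_value(self):
        m = marginal_moments(1.0, 3.0, 0.5)
        assert m.mu == pytest.approx(2.0)
        assert m.var == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "mu1, mu2, pi",
        [(2, 7, 0.3), (1, 3, 0.5), (0.5, 12, 0.8), (5, 5, 0.4)],
    )
    def test_against_brute_force_pmf_sums(self, mu1, mu2, pi):
        m = marginal_moments(mu1, mu2, pi)
        mean_bf, var_bf = brute_force_moments(mu1, mu2, pi)
        assert m.mu == pytest.approx(mean_bf, abs=1e-8)
        assert m.var == pytest.approx(var_bf, abs=1e-8)

    def test_overdispersion_nonnegative(self):
        m = marginal_moments(2.0, 9.0, 0.25)
        assert m.var >= m.mu


class TestEta:
    def test_vanishing_mixture_limit(self):
        p = MarginalizedParams(beta=[0.7], alpha=[0.0], tau=-30.0)
        val = eta(p, [[1.0]], [[1.0]])
        assert val[0] == pytest.approx(np.exp(0.7), rel=1e-10)

    def test_equals_substituted_mu2(self):
        # intercept-only: beta0=log 2, alpha0=0, tau=0 -> mu=2, mu1=1, pi=.5
        p = MarginalizedParams(beta=[np.log(2.0)], alpha=[0.0], tau=0.0)
        val = eta(p, [[1.0]], [[1.0]])[0]
        assert val == pytest.approx(3.0, abs=1e-12)
        assert val == pytest.approx(mu2_from_marginal(2.0, 1.0, 0.5), abs=1e-10)

    def test_sign_flags_invalid_region(self):
        p = MarginalizedParams(beta=[0.0], alpha=[2.0], tau=0.0)
        assert eta(p, [[1.0]], [[1.0]])[0] <= 0


class TestMarginalizedLoglik:
    def test_single_observation_hand_value(self):
        d = DesignData(y=[0], X=[[1.0]], Z=[[1.0]])
        p = MarginalizedParams(beta=[0.0], alpha=[0.0], tau=0.0)
        assert marginalized_loglik(p, d) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_mixture_oracle(self):
        """The marginalized display must equal the latent-class likelihood
        with mu2 substituted, across many random valid parameter sets."""
        rng = np.random.default_rng(7)
        n = 200
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        checked = 0
        while checked < 100:
            beta = rng.normal(0.8, 0.3, 2)
            alpha = rng.normal(0.2, 0.3, 2)
            tau = rng.normal(0.0, 0.8)
            p = MarginalizedParams(beta, alpha, tau)
            e = eta(p, X, X)
            if np.any(e <= 0):
                continue
            y = rng.poisson(np.exp(X @ beta))
            d = DesignData(y=y, X=X, Z=X)
            ll = marginalized_loglik(p, d)
            mu1 = np.exp(X @ alpha)
            mu2 = mu2_from_marginal(np.exp(X @ beta), mu1, p.pi)
            ll_direct = float(np.sum(mixture_log_pmf(y, mu1, mu2, p.pi)))
            assert ll == pytest.approx(ll_direct, abs=1e-8)
            checked += 1

    def test_single_component_limit_is_poisson(self):
        rng = np.random.default_rng(3)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.0, 0.2])
        y = rng.poisson(np.exp(X @ beta))
        d = DesignData(y=y, X=X, Z=X)
        p = MarginalizedParams(beta, [0.0, 0.0], -30.0)
        mu = np.exp(X @ beta)
        from scipy.stats import poisson

        ll_pois = float(np.sum(poisson.logpmf(y, mu)))
        assert marginalized_loglik(p, d) == pytest.approx(ll_pois, abs=1e-6)

    def test_invalid_region_returns_smooth_penalty(self):
        d = DesignData(y=[1], X=[[1.0]], Z=[[1.0]])
        p_bad = MarginalizedParams(beta=[0.0], alpha=[2.0], tau=0.0)
        val, n_bad = marginalized_loglik(p_bad, d, return_validity=True)
        assert n_bad == 1
        assert val <= PENALTY_BASE
        # deeper violation -> lower value (line search can retreat)
        p_worse = MarginalizedParams(beta=[0.0], alpha=[3.0], tau=0.0)
        assert marginalized_loglik(p_worse, d) < val


class TestSimulatedMomentProperties:
    def test_marginalization_property(self):
        """Empirical mean of simulated counts at a fixed profile converges
        to exp(x'beta) regardless of the component split."""
        p = MarginalizedParams(beta=[np.log(3.0)], alpha=[0.3], tau=0.4)
        n = 100_000
        X = np.ones((n, 1))
        y, _ = simulate_counts(X, X, p, seed=99)
        m = marginal_moments(
            float(np.exp(0.3)),
            float(mu2_from_marginal(3.0, np.exp(0.3), p.pi)),
            p.pi,
        )
        mc_se = np.sqrt(m.var / n)
        assert abs(y.mean() - 3.0) < 3 * mc_se

    def test_variance_matches_closed_form(self):
        p = MarginalizedParams(beta=[np.log(3.0)], alpha=[0.0], tau=0.0)
        n = 100_000
        X = np.ones((n, 1))
        y, _ = simulate_counts(X, X, p, seed=17)
        mu2 = mu2_from_marginal(3.0, 1.0, 0.5)
        m = marginal_moments(1.0, mu2, 0.5)
        # variance of the sample variance of iid draws, normal approximation
        assert abs(y.var(ddof=1) - m.var) < 4 * m.var * np.sqrt(2.0 / n) + 0.05
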