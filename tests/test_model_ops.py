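import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aibayes import (
    AlleleCountSet,
    BiasSpec,
    PriorConfig,
    empirical_hyperparams,
    expected_counts,
    fit_gamma_mle,
    log_posterior,
    nb_log_pmf,
    rough_beta_estimates,
    theta_from_alpha,
)
from aibayes.model import ModelState

from helpers import gamma_loglik, gamma_mle_grid

positive = st.floats(0.05, 20.0)


class TestExpectedCounts:
    def test_perfect_assignment_no_imbalance(self):
        assert expected_counts(1.0, 100.0, 1.0, 1.0) == (100.0, 100.0, 0.0)

    def test_direct_substitution(self):
        ex, ey, ez = expected_counts(2.0, 10.0, 0.9, 0.8)
        assert (ex, ey) == (18.0, 4.0)
        assert ez == pytest.approx(3.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(positive, positive, st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    def test_total_conservation(self, alpha, beta, r_m, r_p):
        # rates <= 1: the three means always sum to beta * (alpha + 1/alpha)
        ex, ey, ez = expected_counts(alpha, beta, r_m, r_p)
        assert ex + ey + ez == pytest.approx(beta * (alpha + 1.0 / alpha),
                                             rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_counts(0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            expected_counts(1.0, -1.0, 1.0, 1.0)


class TestTheta:
    @pytest.mark.parametrize("alpha,expected", [
        (1.0, 0.5), (2.0, 0.8), (1e-6, pytest.approx(0.0, abs=1e-11)),
        (1e6, pytest.approx(1.0, abs=1e-11)),
    ])
    def test_known_values(self, alpha, expected):
        assert theta_from_alpha(alpha) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(positive)
    def test_reciprocal_symmetry(self, alpha):
        assert theta_from_alpha(1.0 / alpha) == pytest.approx(
            1.0 - theta_from_alpha(alpha), abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.logspace(-2, 2, 200)
        assert np.all(np.diff(theta_from_alpha(grid)) > 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            theta_from_alpha(0.0)


class TestNbLogPmf:
    def test_known_point(self):
        assert nb_log_pmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5))

    def test_poisson_limit(self):
        k = np.arange(20)
        nb = nb_log_pmf(k, 5.0, 1e-8)
        pois = stats.poisson.logpmf(k, 5.0)
        np.testing.assert_allclose(nb, pois, atol=1e-6)

    def test_normalization(self):
        k = np.arange(5000)
        total = np.exp(nb_log_pmf(k, 5.0, 0.2)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_variance_is_mean_plus_phi_mean_sq(self):
        mu, phi = 7.0, 0.3
        k = np.arange(20000)
        p = np.exp(nb_log_pmf(k, mu, phi))
        var = (p * k**2).sum() - (p * k).sum() ** 2
        assert var == pytest.approx(mu + phi * mu**2, rel=1e-8)

    def test_zero_mean_point_mass(self):
        assert nb_log_pmf(0, 0.0, 0.5) == 0.0
        assert nb_log_pmf(3, 0.0, 0.5) == -np.inf

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 1.0, 1.0)


def _complete_priors():
    return PriorConfig().with_beta_hyperparams(a_beta=2.0, a_bbeta=0.02,
                                               b_bbeta=2.0)


def _state(alpha1=1.0, alpha2=1.0, betas=(100.0, 100.0), phi=0.05):
    return ModelState(alpha1=alpha1, alpha2=alpha2,
                      beta=(np.full(1, betas[0]), np.full(1, betas[1])),
                      b_beta=0.01, phi=phi)


def _data(x1=100, y1=100, z1=4, x2=100, y2=100, z2=4):
    return AlleleCountSet(
        "u", ("a", "b"),
        x=(np.array([x1]), np.array([x2])),
        y=(np.array([y1]), np.array([y2])),
        z=(np.array([z1]), np.array([z2])),
    )


class TestLogPosterior:
    def test_beta_change_touches_only_data_and_beta_terms(self):
        """Doubling beta at alpha=1, r=1 changes data + beta-prior terms only."""
        from aibayes import nb_log_pmf
        priors = _complete_priors()
        bias = BiasSpec.uniform(1.0)
        data = _data(x1=100, y1=100, z1=0, x2=100, y2=100, z2=0)
        st1, st2 = _state(), _state(betas=(200.0, 200.0))
        lp1 = log_posterior(st1, data, bias, priors)
        lp2 = log_posterior(st2, data, bias, priors)
        expected = 0.0
        for counts in (100, 100, 100, 100):  # x and y in both conditions
            expected += nb_log_pmf(counts, 200.0, 0.05) \
                - nb_log_pmf(counts, 100.0, 0.05)
        for b_new, b_old in ((200.0, 100.0), (200.0, 100.0)):
            expected += (stats.gamma.logpdf(b_new, a=2.0, scale=100.0)
                         - stats.gamma.logpdf(b_old, a=2.0, scale=100.0))
        assert lp2 - lp1 == pytest.approx(expected, rel=1e-10)

    def test_label_swap_invariance(self):
        """Swapping alleles, rates and inverting alphas preserves the posterior.

        The data terms are exactly invariant and the lognormal prior is
        symmetric in log alpha, so the alpha-density difference reduces to
        the change-of-variables term 2*log(alpha_i) per condition.
        """
        priors = _complete_priors()
        bias = BiasSpec(r_m=(0.9, 0.92), r_p=(0.85, 0.8))
        data = _data(x1=150, y1=80, z1=20, x2=90, y2=110, z2=15)
        a1, a2 = 1.4, 0.7
        lp = log_posterior(_state(alpha1=a1, alpha2=a2), data, bias, priors)
        lp_sw = log_posterior(_state(alpha1=1 / a1, alpha2=1 / a2),
                              data.swapped_labels(),
                              bias.swapped_labels(), priors)
        jacobian = 2.0 * (np.log(a1) + np.log(a2))
        assert lp_sw - lp == pytest.approx(jacobian, abs=1e-10)

    def test_zero_unassigned_with_full_assignment(self):
        priors = _complete_priors()
        data = _data(z1=0, z2=0)
        lp = log_posterior(_state(), data, BiasSpec.uniform(1.0), priors)
        assert np.isfinite(lp)
        # observed z > 0 with Ez = 0 is impossible under the model
        data_bad = _data(z1=1, z2=0)
        assert log_posterior(_state(), data_bad, BiasSpec.uniform(1.0),
                             priors) == -np.inf

    def test_invalid_state_rejected_not_raised(self):
        priors = _complete_priors()
        bad = _state()
        bad.alpha1 = -1.0
        assert log_posterior(bad, _data(), BiasSpec.uniform(1.0),
                             priors) == -np.inf


class TestRoughBetas:
    def test_half_total(self):
        data = _data(x1=100, y1=100, z1=0, x2=18, y2=4, z2=3)
        b1, b2 = rough_beta_estimates(data)
        assert b1[0] == 100.0
        assert b2[0] == 12.5

    def test_floor_on_empty_replicate(self):
        data = _data(x1=0, y1=0, z1=0)
        b1, _ = rough_beta_estimates(data)
        assert b1[0] == 0.5


class TestGammaMle:
    def test_recovers_parameters_at_large_n(self):
        rng = np.random.default_rng(42)
        draws = rng.gamma(shape=3.0, scale=0.5, size=100_000)  # rate 2
        shape, rate = fit_gamma_mle(draws)
        assert shape == pytest.approx(3.0, rel=0.05)
        assert rate == pytest.approx(2.0, rel=0.05)

    def test_matches_grid_oracle_on_two_points(self):
        values = [1.0, 4.0]
        shape, rate = fit_gamma_mle(values)
        g_shape, g_rate = gamma_mle_grid(values)
        # the dense-grid optimum is within its own resolution of the MLE
        assert np.log(shape) == pytest.approx(np.log(g_shape), abs=0.05)
        assert np.log(rate) == pytest.approx(np.log(g_rate), abs=0.05)
        assert gamma_loglik(values, shape, rate) >= gamma_loglik(
            values, g_shape, g_rate) - 1e-6

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_gamma_mle([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            fit_gamma_mle([1.0])


class TestEmpiricalHyperparams:
    def test_hyperprior_mean_matches_rate_mle(self):
        rng = np.random.default_rng(1)
        beta_hats = rng.gamma(shape=2.0, scale=100.0, size=5000)  # rate 0.01
        priors = empirical_hyperparams(beta_hats, PriorConfig())
        assert priors.a_beta == pytest.approx(2.0, rel=0.1)
        assert priors.a_bbeta / priors.b_bbeta == pytest.approx(0.01, rel=0.1)

    def test_construction_from_rate(self):
        # rate MLE b_hat maps to gamma(2 b_hat, 2), prior mean b_hat
        values = [50.0, 150.0, 100.0, 80.0, 120.0, 90.0]
        _, b_hat = fit_gamma_mle(values)
        priors = empirical_hyperparams(np.array(values), PriorConfig())
        assert priors.a_bbeta == pytest.approx(2.0 * b_hat)
        assert priors.b_bbeta == 2.0
        assert priors.a_bbeta / priors.b_bbeta == pytest.approx(b_hat)

    def test_degenerate_propagates(self):
        with pytest.raises(ValueError):
            empirical_hyperparams(np.full(6, 3.0), PriorConfig())
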