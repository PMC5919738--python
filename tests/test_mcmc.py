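import numpy as np
import pytest

from aibayes import (
    AlleleCountSet,
    BiasSpec,
    EnvironmentalModel,
    McmcSettings,
    PriorConfig,
    summarize,
)
from aibayes.model import Chains, derive_unit_seed

from helpers import grid_mean_ci, reduced_posterior_grid

PRIOR_MEAN_ALPHA = np.exp(1.0 / 32.0)                      # ~1.0317
PRIOR_SD_ALPHA = np.sqrt((np.exp(1 / 16) - 1) * np.exp(1 / 16))  # ~0.2624


def test_same_seed_gives_identical_chains(balanced_unit, default_bias,
                                          fast_settings):
    r1 = EnvironmentalModel(balanced_unit, default_bias).fit(fast_settings)
    r2 = EnvironmentalModel(balanced_unit, default_bias).fit(fast_settings)
    np.testing.assert_array_equal(r1.chains.alpha1, r2.chains.alpha1)
    np.testing.assert_array_equal(r1.chains.phi, r2.chains.phi)
    assert r1.posterior == r2.posterior


def test_different_seeds_differ(balanced_unit, default_bias, fast_settings):
    r1 = EnvironmentalModel(balanced_unit, default_bias).fit(fast_settings)
    r2 = EnvironmentalModel(balanced_unit, default_bias).fit(
        McmcSettings(n_iter=6000, burn_in=2000, seed=8))
    assert not np.array_equal(r1.chains.alpha1, r2.chains.alpha1)


def test_noninformative_data_returns_the_prior(fast_settings):
    """Tiny counts: the posterior of alpha stays close to its prior."""
    unit = AlleleCountSet(
        "tiny", ("a", "b"),
        x=(np.array([1, 0, 0]), np.array([0, 1, 0])),
        y=(np.array([0, 1, 0]), np.array([0, 0, 1])),
        z=(np.array([0, 0, 2]), np.array([2, 0, 0])),
    )
    res = EnvironmentalModel(unit, BiasSpec.uniform(0.9)).fit(
        McmcSettings(n_iter=12000, burn_in=4000, seed=3))
    for draws in (res.chains.alpha1, res.chains.alpha2):
        assert draws.mean() == pytest.approx(PRIOR_MEAN_ALPHA, rel=0.15)
        assert draws.std() == pytest.approx(PRIOR_SD_ALPHA, rel=0.15)
    assert not res.posterior.reject_h01
    assert not res.posterior.reject_h02


def test_strong_imbalance_rejected_in_reduced_model():
    """K=1, phi and beta fixed at truth: heavy maternal excess flags AI."""
    unit = AlleleCountSet(
        "strong", ("a", "b"),
        x=(np.array([1000]), np.array([100])),
        y=(np.array([10]), np.array([100])),
        z=(np.array([0]), np.array([0])),
    )
    priors = PriorConfig().with_beta_hyperparams(1.0, 0.02, 2.0)
    res = EnvironmentalModel(unit, BiasSpec.uniform(1.0), priors).fit(
        McmcSettings(n_iter=12000, burn_in=4000, seed=5),
        fix_phi=0.02,
        fix_beta=(np.array([100.0]), np.array([100.0])),
    )
    assert res.posterior.reject_h01
    assert res.posterior.alpha1.ci_low > 1.0
    assert not res.posterior.reject_h02


def test_reduced_model_matches_grid_integration():
    """MCMC marginal of alpha1 agrees with deterministic integration."""
    x, y, z = 260, 90, 12
    phi, beta = 0.05, 80.0
    r = 0.95
    unit = AlleleCountSet(
        "grid", ("a", "b"),
        x=(np.array([x]), np.array([100])),
        y=(np.array([y]), np.array([110])),
        z=(np.array([z]), np.array([8])),
    )
    priors = PriorConfig().with_beta_hyperparams(1.0, 0.02, 2.0)
    res = EnvironmentalModel(unit, BiasSpec.uniform(r), priors).fit(
        McmcSettings(n_iter=40000, burn_in=5000, seed=11),
        fix_phi=phi, fix_beta=(np.array([beta]), np.array([100.0])),
    )
    alpha, w = reduced_posterior_grid(x, y, z, r, r, phi, beta)
    mean, lo, hi = grid_mean_ci(alpha, w)
    s = res.posterior.alpha1
    assert s.mean == pytest.approx(mean, abs=0.02)
    assert s.ci_low == pytest.approx(lo, abs=0.02)
    assert s.ci_high == pytest.approx(hi, abs=0.02)


def test_acceptance_rates_in_healthy_window(balanced_unit, default_bias,
                                            fast_settings):
    res = EnvironmentalModel(balanced_unit, default_bias).fit(fast_settings)
    assert np.all(res.chains.accept_rates > 0.1)
    assert np.all(res.chains.accept_rates < 0.6)


def test_draw_count_follows_settings(balanced_unit, default_bias):
    settings = McmcSettings(n_iter=5000, burn_in=1000, thin=4, seed=1)
    res = EnvironmentalModel(balanced_unit, default_bias).fit(settings)
    assert len(res.chains) == settings.n_draws == 1000


def test_posterior_spread_shrinks_with_coverage():
    """Ten-fold more reads narrows the alpha posterior (matched seeds)."""
    def unit_at(eta):
        rng = np.random.default_rng(1234)
        x = rng.poisson(eta * np.array([[1.0, 1.2, 0.7], [1.0, 1.3, 0.8]]))
        y = rng.poisson(eta * np.array([[1.0, 1.2, 0.7], [1.0, 1.3, 0.8]]))
        z = rng.poisson(0.04 * eta * np.ones((2, 3)))
        return AlleleCountSet(f"eta{eta}", ("a", "b"),
                              x=(x[0], x[1]), y=(y[0], y[1]),
                              z=(z[0], z[1]))

    fits = {
        eta: EnvironmentalModel(unit_at(eta), BiasSpec.uniform(0.98)).fit(
            McmcSettings(n_iter=8000, burn_in=2000, seed=2))
        for eta in (10, 100)
    }
    assert fits[100].chains.alpha1.std() < fits[10].chains.alpha1.std()


def test_label_swap_reciprocal_distribution(imbalanced_unit, fast_settings):
    """Swapped alleles give alpha draws distributed as the reciprocals."""
    from scipy.stats import ks_2samp

    bias = BiasSpec(r_m=(0.95, 0.97), r_p=(0.93, 0.96))
    res = EnvironmentalModel(imbalanced_unit, bias).fit(fast_settings)
    res_sw = EnvironmentalModel(imbalanced_unit.swapped_labels(),
                                bias.swapped_labels()).fit(fast_settings)
    ks = ks_2samp(1.0 / res_sw.chains.alpha1, res.chains.alpha1).statistic
    assert ks < 0.05


def test_summarize_reject_rules():
    settings = McmcSettings(n_iter=20, burn_in=10, seed=0)
    const = np.full(10, 1.5)
    sym = np.array([0.8, 0.9, 0.95, 1.0, 1.05, 1.1, 1.2, 0.85, 1.15, 1.0])
    ones = np.ones(10)
    beta = np.ones((10, 2))

    s = summarize(Chains(alpha1=const, alpha2=ones, beta=beta,
                         b_beta=ones, phi=ones, accept_rates=np.array([0.3]),
                         n_reps=(1, 1), settings=settings), unit_id="c")
    assert s.reject_h01 and s.alpha1.ci_low == s.alpha1.ci_high == 1.5

    s = summarize(Chains(alpha1=sym, alpha2=ones, beta=beta, b_beta=ones,
                         phi=ones, accept_rates=np.array([0.3]),
                         n_reps=(1, 1), settings=settings), unit_id="s")
    assert not s.reject_h01

    # closed-interval convention: a CI touching 1 does not reject
    touching = np.concatenate([np.ones(5), np.full(5, 1.3)])
    s = summarize(Chains(alpha1=touching, alpha2=ones, beta=beta,
                         b_beta=ones, phi=ones, accept_rates=np.array([0.3]),
                         n_reps=(1, 1), settings=settings), unit_id="t")
    assert s.alpha_ratio.ci_low == 1.0
    assert not s.reject_h03


def test_unit_seed_derivation_is_stable_and_bounded():
    s1 = derive_unit_seed(42, "exon1:line3")
    assert s1 == derive_unit_seed(42, "exon1:line3")
    assert s1 != derive_unit_seed(43, "exon1:line3")
    assert s1 != derive_unit_seed(42, "exon1:line4")
    assert 0 <= s1 < 2**31
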