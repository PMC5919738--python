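"""Hierarchical negative-binomial model of allelic imbalance in two conditions.

The model per unit: for condition ``i`` and replicate ``k`` the counts
are independent negative binomials with a common dispersion ``phi``,

    x_{i,k} ~ NB(mean = alpha_i * beta_{i,k} * r_{i,m},       var = mu + phi mu^2)
    y_{i,k} ~ NB(mean = beta_{i,k} * r_{i,p} / alpha_i,        ...)
    z_{i,k} ~ NB(mean = [(1-r_{i,p})/alpha_i + (1-r_{i,m}) alpha_i] beta_{i,k})

``alpha_i`` measures allelic imbalance in condition ``i`` (alpha = 1 is
balance; alpha_i**2 is the bias-corrected maternal/paternal mean ratio),
``beta_{i,k}`` is a replicate-level expression scale and the assignment
rates ``r`` encode mapping bias. The unassigned counts ``z`` enter the
likelihood and sharpen the dispersion estimate. Three credible-interval
tests are read off the posterior: H01 (alpha1 = 1), H02 (alpha2 = 1)
and H03 (alpha1 = alpha2), the latter being a formal test of an
imbalance-by-condition (G-by-E) interaction.

Typical use::

    model = EnvironmentalModel(counts, bias)
    res = model.fit(McmcSettings(seed=1))
    print(res.summary())
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from . import _sampler
from .datatypes import (
    AlleleCountSet,
    BiasSpec,
    McmcSettings,
    ParamSummary,
    PosteriorSummary,
    PriorConfig,
)

__all__ = [
    "ModelState",
    "Chains",
    "expected_counts",
    "theta_from_alpha",
    "nb_log_pmf",
    "log_posterior",
    "rough_beta_estimates",
    "fit_gamma_mle",
    "empirical_hyperparams",
    "run_mcmc",
    "summarize",
    "effective_sample_size",
    "derive_unit_seed",
    "EnvironmentalModel",
    "EnvironmentalResults",
]


def expected_counts(alpha: float, beta: float, r_m: float, r_p: float):
    """Mean maternal/paternal/unassigned counts for one replicate.

    ``Ez`` is floored at 0; the bracket can only go negative when a rate
    above 1 is supplied (misspecification harness). With rates <= 1 the
    three means always sum to ``beta * (alpha + 1/alpha)``, the expected
    total read count of the replicate.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError("alpha and beta must be strictly positive")
    if not (r_m > 0 and r_p > 0):
        raise ValueError("assignment rates must be strictly positive")
    ex = alpha * beta * r_m
    ey = beta * r_p / alpha
    ez = ((1.0 - r_p) / alpha + (1.0 - r_m) * alpha) * beta
    return ex, ey, max(ez, 0.0)


def theta_from_alpha(alpha):
    """Maternal expression proportion theta = alpha^2 / (alpha^2 + 1).

    Strictly increasing in alpha; 0.5 at perfect balance, tending to 0
    (1) when no (all) expression comes from the maternal allele.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    out = alpha**2 / (alpha**2 + 1.0)
    return float(out) if out.ndim == 0 else out


def nb_log_pmf(k, mean, phi):
    """Log pmf of NB(mean, dispersion): variance = mean + phi * mean**2.

    A zero mean degenerates to a point mass at zero. Vectorized over ``k``.
    """
    if phi <= 0:
        raise ValueError("phi must be > 0")
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("counts must be non-negative")
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if mean == 0:
        out = np.where(k == 0, 0.0, -np.inf)
        return float(out) if out.ndim == 0 else out
    inv = 1.0 / phi
    lpm = np.log1p(phi * mean)
    out = (special.gammaln(k + inv) - special.gammaln(inv)
           - special.gammaln(k + 1.0) - inv * lpm
           + k * (np.log(phi * mean) - lpm))
    return float(out) if out.ndim == 0 else out


@dataclass
class ModelState:
    """One point in parameter space of the two-condition model."""

    alpha1: float
    alpha2: float
    beta: tuple[np.ndarray, np.ndarray]
    b_beta: float
    phi: float

    def __post_init__(self) -> None:
        self.beta = tuple(np.asarray(b, dtype=float) for b in self.beta)

    @property
    def valid(self) -> bool:
        return (self.alpha1 > 0 and self.alpha2 > 0 and self.b_beta > 0
                and self.phi > 0
                and all((b > 0).all() for b in self.beta))


def log_posterior(state: ModelState, data: AlleleCountSet, bias: BiasSpec,
                  priors: PriorConfig) -> float:
    """Unnormalized log posterior density at ``state``.

    Sum of the NB log likelihood of all counts at their model means plus
    the log prior densities (lognormal for the alphas, gamma for the
    betas and b_beta, inverse-gamma for phi). Invalid states return
    ``-inf`` rather than raising, so samplers can reject them.
    """
    if not priors.complete:
        raise ValueError("priors incomplete: run empirical_hyperparams first")
    if not state.valid:
        return -np.inf
    lp = 0.0
    alphas = (state.alpha1, state.alpha2)
    for i in range(2):
        for k in range(data.n_reps[i]):
            ex, ey, ez = expected_counts(alphas[i], state.beta[i][k],
                                         bias.r_m[i], bias.r_p[i])
            if ez == 0.0 and (bias.r_m[i] > 1 or bias.r_p[i] > 1):
                # negative bracket floored: keep the likelihood proper
                ez = _sampler.EZ_FLOOR
            lp += nb_log_pmf(data.x[i][k], ex, state.phi)
            lp += nb_log_pmf(data.y[i][k], ey, state.phi)
            lp += nb_log_pmf(data.z[i][k], ez, state.phi)
            lp += stats.gamma.logpdf(state.beta[i][k], a=priors.a_beta,
                                     scale=1.0 / state.b_beta)
        lp += stats.lognorm.logpdf(alphas[i],
                                   s=np.sqrt(priors.sigma2_alpha),
                                   scale=np.exp(priors.mu_alpha))
    lp += stats.gamma.logpdf(state.b_beta, a=priors.a_bbeta,
                             scale=1.0 / priors.b_bbeta)
    lp += stats.invgamma.logpdf(state.phi, a=priors.a_phi,
                                scale=priors.b_phi)
    return float(lp)


def rough_beta_estimates(data: AlleleCountSet) -> tuple[np.ndarray, np.ndarray]:
    """Crude per-replicate expression scales used to seed empirical Bayes.

    Since the expected total count of a replicate is beta*(alpha + 1/alpha),
    which equals 2*beta at balance with full assignment, half the observed
    total is an adequate rough estimate. Floored at 0.5 to avoid zeros.
    """
    return tuple(
        np.maximum((data.x[i] + data.y[i] + data.z[i]) / 2.0, 0.5).astype(float)
        for i in range(2)
    )


def fit_gamma_mle(values: Sequence[float]) -> tuple[float, float]:
    """Maximum-likelihood (shape, rate) of a gamma distribution.

    Solves the profile score equation ``log(a) - digamma(a) = log(mean) -
    mean(log)`` for the shape, then sets rate = shape / mean. Requires at
    least two values with nonzero spread.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(v <= 0):
        raise ValueError("values must be strictly positive")
    s = np.log(v.mean()) - np.log(v).mean()
    if s <= 0:  # zero variance (all values equal)
        raise ValueError("values have zero spread; gamma MLE is degenerate")
    # Minka-style initialization, then solve on the log-shape scale
    a0 = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    sol = optimize.root_scalar(
        lambda la: la - special.digamma(np.exp(la)) - s,
        x0=np.log(a0), x1=np.log(a0) + 0.1, method="secant", xtol=1e-12,
    )
    shape = float(np.exp(sol.root))
    return shape, shape / float(v.mean())


def empirical_hyperparams(beta_hats, priors: PriorConfig) -> PriorConfig:
    """Set the beta-prior hyperparameters from rough per-replicate scales.

    Fits gamma(shape, rate) to the rough beta estimates by ML; the shape
    becomes ``a_beta`` and the hyperprior of the rate ``b_beta`` is
    gamma(2*rate_hat, 2), whose mean is the ML rate — so with no other
    information the beta prior is centred on the empirical fit while
    ``b_beta`` remains free to pool strength across replicates.
    """
    if isinstance(beta_hats, tuple):
        beta_hats = np.concatenate(beta_hats)
    a_hat, b_hat = fit_gamma_mle(beta_hats)
    return priors.with_beta_hyperparams(a_beta=a_hat, a_bbeta=2.0 * b_hat,
                                        b_bbeta=2.0)


@dataclass
class Chains:
    """Post-burn-in, thinned posterior draws for one unit."""

    alpha1: np.ndarray
    alpha2: np.ndarray
    beta: np.ndarray          # (n_draws, K1 + K2)
    b_beta: np.ndarray
    phi: np.ndarray
    accept_rates: np.ndarray  # per sampled site
    n_reps: tuple[int, int]
    settings: McmcSettings

    @property
    def ratio(self) -> np.ndarray:
        return self.alpha1 / self.alpha2

    @property
    def theta1(self) -> np.ndarray:
        return theta_from_alpha(self.alpha1)

    @property
    def theta2(self) -> np.ndarray:
        return theta_from_alpha(self.alpha2)

    def __len__(self) -> int:
        return self.alpha1.size


def run_mcmc(data: AlleleCountSet, bias: BiasSpec, priors: PriorConfig,
             settings: McmcSettings = McmcSettings(),
             fix_phi: float | None = None,
             fix_beta: tuple[np.ndarray, np.ndarray] | None = None) -> Chains:
    """Sample the posterior for one unit with Metropolis-within-Gibbs.

    ``fix_phi`` / ``fix_beta`` pin those parameters at given values
    instead of sampling them (used for reduced-model checks against
    deterministic integration). Bit-reproducible given ``settings.seed``.
    """
    if not priors.complete:
        raise ValueError("priors incomplete: run empirical_hyperparams first")
    k1, k2 = data.n_reps
    n_par = 2 + k1 + k2 + 2
    init = np.zeros(n_par)
    update = np.ones(n_par, dtype=np.bool_)

    # start the alphas at their empirical estimates: the posterior can be
    # bimodal (large imbalance traded against inflated dispersion), and a
    # chain started at alpha = 1 can stick in the spurious mode
    alpha0 = np.empty(2)
    for i in range(2):
        num = (data.x[i].sum() + 0.5) / bias.r_m[i]
        den = (data.y[i].sum() + 0.5) / bias.r_p[i]
        alpha0[i] = np.clip(np.sqrt(num / den), 0.02, 50.0)
    init[0], init[1] = np.log(alpha0)

    if fix_beta is not None:
        beta0 = np.concatenate([np.asarray(b, float) for b in fix_beta])
        update[2:2 + k1 + k2] = False
        update[2 + k1 + k2] = False  # b_beta has no role with beta fixed
    else:
        scale = np.repeat(alpha0 + 1.0 / alpha0, (k1, k2))
        totals = np.concatenate([
            data.x[i] + data.y[i] + data.z[i] for i in range(2)])
        beta0 = np.maximum(totals / scale, 0.5)
    init[2:2 + k1 + k2] = np.log(beta0)
    init[2 + k1 + k2] = np.log(priors.a_bbeta / priors.b_bbeta)
    if fix_phi is not None:
        if fix_phi <= 0:
            raise ValueError("fix_phi must be > 0")
        init[-1] = np.log(fix_phi)
        update[-1] = False
    else:
        init[-1] = np.log(priors.b_phi / (priors.a_phi - 1.0)
                          if priors.a_phi > 1 else priors.b_phi)

    draws, rates = _sampler.run_env_chain(
        data.x[0].astype(float), data.y[0].astype(float),
        data.z[0].astype(float),
        data.x[1].astype(float), data.y[1].astype(float),
        data.z[1].astype(float),
        float(bias.r_m[0]), float(bias.r_p[0]),
        float(bias.r_m[1]), float(bias.r_p[1]),
        priors.mu_alpha, priors.sigma2_alpha, priors.a_phi, priors.b_phi,
        priors.a_beta, priors.a_bbeta, priors.b_bbeta,
        init, update,
        settings.n_iter, settings.burn_in, settings.thin,
        int(settings.seed) % (2**32), settings.adapt, settings.target_accept,
    )
    return Chains(
        alpha1=draws[:, 0], alpha2=draws[:, 1],
        beta=draws[:, 2:2 + k1 + k2],
        b_beta=draws[:, 2 + k1 + k2], phi=draws[:, -1],
        accept_rates=rates[np.asarray(update)],
        n_reps=(k1, k2), settings=settings,
    )


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS from Geyer's initial monotone positive sequence of autocorrelations.

    tau = -1 + 2 * sum_m Gamma_m with pair sums Gamma_m = rho_{2m} +
    rho_{2m+1}, truncated at the first negative pair and forced
    non-increasing; ESS = n / max(tau, 1).
    """
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    if not np.any(x):
        return float(n)
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    n_pairs = (n - 1) // 2
    tau = -1.0
    prev = np.inf
    for j in range(n_pairs):
        g = rho[2 * j] + rho[2 * j + 1]
        if g < 0:
            break
        g = min(g, prev)
        tau += 2.0 * g
        prev = g
    return float(n / max(tau, 1.0))


def derive_unit_seed(master_seed: int, unit_id: str) -> int:
    """Stable per-unit seed below 2**31 from (master seed, unit id)."""
    h = hashlib.sha256(f"{master_seed}:{unit_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _param_summary(draws: np.ndarray, level: float) -> ParamSummary:
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
    return ParamSummary(
        mean=float(draws.mean()), median=float(np.median(draws)),
        ci_low=float(lo), ci_high=float(hi),
        ess=effective_sample_size(draws),
    )


def summarize(chains: Chains, level: float = 0.95,
              unit_id: str = "") -> PosteriorSummary:
    """Equal-tailed credible intervals and the three tests from the chains.

    A hypothesis is rejected when the corresponding closed credible
    interval does not contain 1 (an interval merely touching 1 does not
    reject). A low-ESS warning (< 100 for alpha1/alpha2) flags chains too
    short to trust.
    """
    if len(chains) == 0:
        raise ValueError("empty chains")
    alpha1 = _param_summary(chains.alpha1, level)
    alpha2 = _param_summary(chains.alpha2, level)
    ratio = _param_summary(chains.ratio, level)
    theta1 = _param_summary(chains.theta1, level)
    theta2 = _param_summary(chains.theta2, level)
    return PosteriorSummary(
        unit_id=unit_id, level=level,
        alpha1=alpha1, alpha2=alpha2, alpha_ratio=ratio,
        theta1=theta1, theta2=theta2,
        reject_h01=not alpha1.contains(1.0),
        reject_h02=not alpha2.contains(1.0),
        reject_h03=not ratio.contains(1.0),
        low_ess_warning=ratio.ess < 100,
    )


class EnvironmentalModel:
    """Two-condition allelic-imbalance model for one genomic unit.

    Parameters
    ----------
    data : AlleleCountSet
        Maternal/paternal/unassigned counts per condition and replicate.
    bias : BiasSpec, optional
        Assignment rates per condition; defaults to perfect assignment.
    priors : PriorConfig, optional
        Hyperparameters; any unset beta-prior values are filled in by
        empirical Bayes at fit time.
    """

    def __init__(self, data: AlleleCountSet, bias: BiasSpec | None = None,
                 priors: PriorConfig | None = None):
        self.data = data
        self.bias = bias if bias is not None else BiasSpec.uniform(1.0)
        self.priors = priors if priors is not None else PriorConfig()

    @classmethod
    def from_dataframe(cls, df, unit_id: str | None = None, **kwargs):
        """Build from a DataFrame with the count-table columns.

        The frame must contain the columns of the count-table dialect
        (see :mod:`aibayes.io`); if it holds several units, ``unit_id``
        selects one.
        """
        import io as _io

        from .io import read_counts_table

        sub = df if unit_id is None else df[df["unit_id"] == unit_id]
        buf = _io.StringIO()
        sub.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        sets = read_counts_table(buf)
        if len(sets) != 1:
            raise ValueError(
                f"expected one unit, found {len(sets)}; pass unit_id")
        return cls(sets[0], **kwargs)

    def fit(self, settings: McmcSettings = McmcSettings(),
            level: float = 0.95, fix_phi: float | None = None,
            fix_beta=None) -> "EnvironmentalResults":
        """Empirical-Bayes hyperparameters, MCMC, posterior summary."""
        priors = self.priors
        if not priors.complete:
            priors = empirical_hyperparams(rough_beta_estimates(self.data),
                                           priors)
        chains = run_mcmc(self.data, self.bias, priors, settings,
                          fix_phi=fix_phi, fix_beta=fix_beta)
        summary = summarize(chains, level=level, unit_id=self.data.unit_id)
        return EnvironmentalResults(self, priors, chains, summary)


@dataclass
class EnvironmentalResults:
    """Fit results: posterior chains, summaries and test decisions."""

    model: EnvironmentalModel
    priors: PriorConfig
    chains: Chains
    posterior: PosteriorSummary

    @property
    def params(self) -> dict[str, float]:
        """Posterior means of the headline parameters."""
        s = self.posterior
        return {
            "alpha1": s.alpha1.mean, "alpha2": s.alpha2.mean,
            "alpha_ratio": s.alpha_ratio.mean,
            "theta1": s.theta1.mean, "theta2": s.theta2.mean,
        }

    def conf_int(self) -> dict[str, tuple[float, float]]:
        """Equal-tailed credible intervals at the summary's level."""
        s = self.posterior
        return {
            name: (getattr(s, name).ci_low, getattr(s, name).ci_high)
            for name in ("alpha1", "alpha2", "alpha_ratio",
                         "theta1", "theta2")
        }

    def summary(self) -> str:
        """Readable per-unit report of estimates, intervals and tests."""
        s = self.posterior
        lines = [
            f"Allelic imbalance model — unit {s.unit_id or '(unnamed)'}",
            f"replicates: K1={self.chains.n_reps[0]}, "
            f"K2={self.chains.n_reps[1]}; draws: {len(self.chains)}; "
            f"credible level: {s.level:.0%}",
            "",
            f"{'parameter':<12}{'mean':>10}{'median':>10}"
            f"{'ci_low':>10}{'ci_high':>10}{'ess':>8}",
        ]
        for name in ("alpha1", "alpha2", "alpha_ratio", "theta1", "theta2"):
            p: ParamSummary = getattr(s, name)
            lines.append(
                f"{name:<12}{p.mean:>10.4f}{p.median:>10.4f}"
                f"{p.ci_low:>10.4f}{p.ci_high:>10.4f}{p.ess:>8.0f}"
            )
        lines += [
            "",
            f"H01 (alpha1 = 1):        {'reject' if s.reject_h01 else 'retain'}",
            f"H02 (alpha2 = 1):        {'reject' if s.reject_h02 else 'retain'}",
            f"H03 (alpha1 = alpha2):   {'reject' if s.reject_h03 else 'retain'}",
        ]
        if s.low_ess_warning:
            lines.append("warning: effective sample size < 100 for "
                         "alpha1/alpha2; lengthen the chain")
        return "\n".join(lines)
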