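"""Adaptive random-walk Metropolis-within-Gibbs samplers (numba kernels).

All parameters are updated one at a time on the log scale; proposal step
sizes are tuned toward a target acceptance rate in batches of 50
iterations during burn-in and frozen afterwards. The kernels are
deterministic given the seed.

Parameter vector layout for the two-condition hierarchical NB model::

    [log a1, log a2, log b_{1,1..K1}, log b_{2,1..K2}, log b_beta, log phi]

and for the single-condition Poisson baseline::

    [log mu, log alpha, log b_1..K]
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG_2PI = math.log(2.0 * math.pi)
EZ_FLOOR = 1e-8  # mean floor when misspecified rates > 1 turn Ez negative


@njit(cache=True)
def nb_logpmf(k: float, mu: float, phi: float) -> float:
    """Negative binomial log pmf, mean/dispersion form (var = mu + phi*mu^2).

    A zero mean degenerates to a point mass at zero.
    """
    if mu <= 0.0:
        return 0.0 if k == 0.0 else -np.inf
    inv = 1.0 / phi
    lpm = math.log1p(phi * mu)
    return (math.lgamma(k + inv) - math.lgamma(inv) - math.lgamma(k + 1.0)
            - inv * lpm + k * (math.log(phi * mu) - lpm))


@njit(cache=True)
def poisson_logpmf(k: float, mu: float) -> float:
    if mu <= 0.0:
        return 0.0 if k == 0.0 else -np.inf
    return k * math.log(mu) - mu - math.lgamma(k + 1.0)


@njit(cache=True)
def _triple_logp(x: float, y: float, z: float, alpha: float, beta: float,
                 rm: float, rp: float, phi: float) -> float:
    """Joint NB log likelihood of one replicate's (x, y, z) counts."""
    ex = alpha * beta * rm
    ey = beta * rp / alpha
    ez = ((1.0 - rp) / alpha + (1.0 - rm) * alpha) * beta
    if ez < 0.0:  # only reachable with rates > 1 (misspecification harness)
        ez = EZ_FLOOR
    return (nb_logpmf(x, ex, phi) + nb_logpmf(y, ey, phi)
            + nb_logpmf(z, ez, phi))


@njit(cache=True)
def _gamma_logpdf_log(lv: float, a: float, b: float) -> float:
    """log density of v = exp(lv) under gamma(shape a, rate b), with Jacobian."""
    return a * lv - b * math.exp(lv) + a * math.log(b) - math.lgamma(a)


@njit(cache=True)
def _env_site_logp(site: int, p: np.ndarray,
                   x1, y1, z1, x2, y2, z2,
                   rm1, rp1, rm2, rp2,
                   mu_a, s2_a, a_phi, b_phi, a_beta, a_bb, b_bb) -> float:
    k1 = x1.shape[0]
    k2 = x2.shape[0]
    nb_site = 2 + k1 + k2  # index of log b_beta
    phi = math.exp(p[nb_site + 1])
    a1 = math.exp(p[0])
    a2 = math.exp(p[1])
    lp = 0.0
    if site == 0:
        for k in range(k1):
            lp += _triple_logp(x1[k], y1[k], z1[k], a1, math.exp(p[2 + k]),
                               rm1, rp1, phi)
        lp += -0.5 * (LOG_2PI + math.log(s2_a)) \
            - 0.5 * (p[0] - mu_a) ** 2 / s2_a
    elif site == 1:
        for k in range(k2):
            lp += _triple_logp(x2[k], y2[k], z2[k], a2,
                               math.exp(p[2 + k1 + k]), rm2, rp2, phi)
        lp += -0.5 * (LOG_2PI + math.log(s2_a)) \
            - 0.5 * (p[1] - mu_a) ** 2 / s2_a
    elif site < 2 + k1:
        k = site - 2
        beta = math.exp(p[site])
        b_beta = math.exp(p[nb_site])
        lp += _triple_logp(x1[k], y1[k], z1[k], a1, beta, rm1, rp1, phi)
        lp += _gamma_logpdf_log(p[site], a_beta, b_beta)
    elif site < nb_site:
        k = site - 2 - k1
        beta = math.exp(p[site])
        b_beta = math.exp(p[nb_site])
        lp += _triple_logp(x2[k], y2[k], z2[k], a2, beta, rm2, rp2, phi)
        lp += _gamma_logpdf_log(p[site], a_beta, b_beta)
    elif site == nb_site:
        b_beta = math.exp(p[site])
        for j in range(k1 + k2):
            lp += _gamma_logpdf_log(p[2 + j], a_beta, b_beta)
        lp += _gamma_logpdf_log(p[site], a_bb, b_bb)
    else:  # log phi
        for k in range(k1):
            lp += _triple_logp(x1[k], y1[k], z1[k], a1, math.exp(p[2 + k]),
                               rm1, rp1, phi)
        for k in range(k2):
            lp += _triple_logp(x2[k], y2[k], z2[k], a2,
                               math.exp(p[2 + k1 + k]), rm2, rp2, phi)
        # inverse-gamma(a_phi, b_phi) on phi, with Jacobian
        lp += (a_phi * math.log(b_phi) - math.lgamma(a_phi)
               - a_phi * p[site] - b_phi / phi)
    return lp


@njit(cache=True)
def run_env_chain(x1, y1, z1, x2, y2, z2,
                  rm1, rp1, rm2, rp2,
                  mu_a, s2_a, a_phi, b_phi, a_beta, a_bb, b_bb,
                  init, update,
                  n_iter, burn_in, thin, seed, adapt, target_accept):
    """Sample the hierarchical NB model; returns (draws, acceptance rates).

    ``init`` is the initial parameter vector (log scale), ``update`` a
    boolean mask selecting which sites are sampled (fixed-parameter modes
    keep a site at its initial value). Draws are returned on the natural
    (exponentiated) scale.
    """
    np.random.seed(seed)
    n_par = init.shape[0]
    p = init.copy()
    lstep = np.full(n_par, math.log(0.25))
    n_draws = (n_iter - burn_in) // thin
    draws = np.empty((n_draws, n_par))
    acc_batch = np.zeros(n_par)
    try_batch = np.zeros(n_par)
    acc_post = np.zeros(n_par)
    try_post = np.zeros(n_par)
    batch_no = 0
    stored = 0
    for it in range(n_iter):
        for site in range(n_par):
            if not update[site]:
                continue
            cur = _env_site_logp(site, p, x1, y1, z1, x2, y2, z2,
                                 rm1, rp1, rm2, rp2,
                                 mu_a, s2_a, a_phi, b_phi,
                                 a_beta, a_bb, b_bb)
            old = p[site]
            p[site] = old + math.exp(lstep[site]) * np.random.normal()
            new = _env_site_logp(site, p, x1, y1, z1, x2, y2, z2,
                                 rm1, rp1, rm2, rp2,
                                 mu_a, s2_a, a_phi, b_phi,
                                 a_beta, a_bb, b_bb)
            accepted = math.log(np.random.random()) < new - cur
            if not accepted:
                p[site] = old
            if it < burn_in:
                try_batch[site] += 1.0
                if accepted:
                    acc_batch[site] += 1.0
            else:
                try_post[site] += 1.0
                if accepted:
                    acc_post[site] += 1.0
        if adapt and it < burn_in and (it + 1) % 50 == 0:
            batch_no += 1
            delta = 1.0 / math.sqrt(batch_no)
            if delta > 0.05:
                delta = 0.05
            for site in range(n_par):
                if try_batch[site] > 0:
                    rate = acc_batch[site] / try_batch[site]
                    lstep[site] += delta if rate > target_accept else -delta
                acc_batch[site] = 0.0
                try_batch[site] = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0 and stored < n_draws:
            for j in range(n_par):
                draws[stored, j] = math.exp(p[j])
            stored += 1
    rates = np.zeros(n_par)
    for site in range(n_par):
        if try_post[site] > 0:
            rates[site] = acc_post[site] / try_post[site]
    return draws, rates


@njit(cache=True)
def _base_site_logp(site: int, p: np.ndarray, x, y, q,
                    a0: float, b0: float) -> float:
    """Poisson baseline: x_k ~ Pois(mu*b_k*(1-q)), y_k ~ Pois(mu*a*b_k*q)."""
    kk = x.shape[0]
    mu = math.exp(p[0])
    alpha = math.exp(p[1])
    lp = _gamma_logpdf_log(p[site], a0, b0)
    if site <= 1:
        for k in range(kk):
            bk = math.exp(p[2 + k])
            lp += poisson_logpmf(x[k], mu * bk * (1.0 - q))
            lp += poisson_logpmf(y[k], mu * alpha * bk * q)
    else:
        k = site - 2
        bk = math.exp(p[site])
        lp += poisson_logpmf(x[k], mu * bk * (1.0 - q))
        lp += poisson_logpmf(y[k], mu * alpha * bk * q)
    return lp


@njit(cache=True)
def run_baseline_chain(x, y, q, a0, b0, init,
                       n_iter, burn_in, thin, seed, adapt, target_accept):
    """Sample the Poisson baseline model; returns (draws, acceptance rates)."""
    np.random.seed(seed)
    n_par = init.shape[0]
    p = init.copy()
    lstep = np.full(n_par, math.log(0.25))
    n_draws = (n_iter - burn_in) // thin
    draws = np.empty((n_draws, n_par))
    acc_batch = np.zeros(n_par)
    acc_post = np.zeros(n_par)
    try_post = 0.0
    batch_no = 0
    stored = 0
    for it in range(n_iter):
        for site in range(n_par):
            cur = _base_site_logp(site, p, x, y, q, a0, b0)
            old = p[site]
            p[site] = old + math.exp(lstep[site]) * np.random.normal()
            new = _base_site_logp(site, p, x, y, q, a0, b0)
            accepted = math.log(np.random.random()) < new - cur
            if not accepted:
                p[site] = old
            if it < burn_in:
                if accepted:
                    acc_batch[site] += 1.0
            elif accepted:
                acc_post[site] += 1.0
        if it >= burn_in:
            try_post += 1.0
        if adapt and it < burn_in and (it + 1) % 50 == 0:
            batch_no += 1
            delta = 1.0 / math.sqrt(batch_no)
            if delta > 0.05:
                delta = 0.05
            for site in range(n_par):
                rate = acc_batch[site] / 50.0
                lstep[site] += delta if rate > target_accept else -delta
                acc_batch[site] = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0 and stored < n_draws:
            for j in range(n_par):
                draws[stored, j] = math.exp(p[j])
            stored += 1
    rates = acc_post / try_post if try_post > 0 else acc_post
    return draws, rates
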