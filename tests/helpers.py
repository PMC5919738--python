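"""Independent oracles used by the test suite.

Everything here is deliberately naive (enumeration, dense grids, exact
rational arithmetic) and shares no code with the package paths it
checks.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy import special, stats


def fisher_greater_exact(a, b, c, d) -> Fraction:
    """One-sided (odds ratio > 1) Fisher p by exact hypergeometric tail."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    p = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        p += Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
    return p


def fisher_less_exact(a, b, c, d) -> Fraction:
    return fisher_greater_exact(b, a, d, c)


def brute_force_rates(mat: str, pat: str, read_len: int):
    """Assignment rates by direct enumeration with numpy comparisons."""
    m = np.frombuffer(mat.upper().encode(), dtype="S1")
    p = np.frombuffer(pat.upper().encode(), dtype="S1")
    n_starts = len(m) - read_len + 1
    hits_m = hits_p = 0
    for s in range(n_starts):
        wm, wp = m[s:s + read_len], p[s:s + read_len]
        usable = (wm != b"N") & (wp != b"N")
        mism = int((wm[usable] != wp[usable]).sum())
        # a read from either haplotype has 0 mismatches to its origin and
        # `mism` to the other; it is assigned iff mism > 0
        if mism > 0:
            hits_m += 1
            hits_p += 1
    return hits_m / n_starts, hits_p / n_starts


def gamma_loglik(values, shape, rate) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.sum(stats.gamma.logpdf(v, a=shape, scale=1.0 / rate)))


def gamma_mle_grid(values, lo=0.01, hi=50.0, n=400):
    """Dense 2-D grid maximization of the gamma likelihood."""
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n))
    best, arg = -np.inf, (None, None)
    for a in grid:
        for b in grid:
            ll = gamma_loglik(values, a, b)
            if ll > best:
                best, arg = ll, (a, b)
    return arg


def reduced_posterior_grid(x, y, z, r_m, r_p, phi, beta,
                           sigma2_alpha=1.0 / 16.0, n_grid=2001,
                           span=3.0):
    """Posterior of alpha on a dense log grid, one condition, K=1.

    phi and beta are fixed at truth; the posterior over alpha factorizes
    across conditions, so the single-condition marginal is exact for the
    two-condition reduced model. Returns (alpha grid, normalized weights).
    """
    la = np.linspace(-span, span, n_grid)
    alpha = np.exp(la)
    ex = alpha * beta * r_m
    ey = beta * r_p / alpha
    ez = ((1.0 - r_p) / alpha + (1.0 - r_m) * alpha) * beta

    def nb(k, mu):
        inv = 1.0 / phi
        out = np.where(
            mu > 0,
            special.gammaln(k + inv) - special.gammaln(inv)
            - special.gammaln(k + 1.0)
            - inv * np.log1p(phi * np.maximum(mu, 1e-300))
            + k * (np.log(np.maximum(phi * mu, 1e-300))
                   - np.log1p(phi * np.maximum(mu, 1e-300))),
            np.where(k == 0, 0.0, -np.inf),
        )
        return out

    logw = nb(x, ex) + nb(y, ey) + nb(z, ez) - 0.5 * la**2 / sigma2_alpha
    logw -= logw.max()
    w = np.exp(logw)
    return alpha, w / w.sum()


def grid_mean_ci(alpha, w, level=0.95):
    mean = float((alpha * w).sum())
    cdf = np.cumsum(w)
    lo = float(np.interp((1 - level) / 2, cdf, alpha))
    hi = float(np.interp(1 - (1 - level) / 2, cdf, alpha))
    return mean, lo, hi
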