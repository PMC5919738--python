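"""Single-condition Poisson baseline model of allelic imbalance.

The comparator model: unassigned reads are discarded and, per replicate
``k`` of one condition,

    x_k ~ Poisson(mu * beta_k * (1 - q))      (maternal)
    y_k ~ Poisson(mu * alpha * beta_k * q)    (paternal)

with independent gamma(1/2, 1/2) priors on ``mu``, ``alpha`` and each
``beta_k``. ``q`` is a fixed, known constant: the expected paternal
share of assigned reads under allelic balance, so ``alpha != 1`` is
evidence of imbalance. Across two conditions the baseline offers only a
descriptive comparison: a unit is said to change imbalance when exactly
one of the two per-condition fits flags it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _sampler
from .datatypes import McmcSettings, ParamSummary
from .model import effective_sample_size

__all__ = [
    "BaselineState",
    "baseline_log_posterior",
    "run_baseline",
    "descriptive_gxe",
    "BaselineModel",
    "BaselineResults",
]

_PRIOR_SHAPE = 0.5
_PRIOR_RATE = 0.5


@dataclass
class BaselineState:
    """One point in baseline parameter space."""

    mu: float
    alpha: float
    beta: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")

    @property
    def valid(self) -> bool:
        return self.mu > 0 and self.alpha > 0 and (self.beta > 0).all()


def baseline_log_posterior(state: BaselineState, x, y) -> float:
    """Unnormalized log posterior of the baseline model; -inf if invalid.

    Unassigned counts never enter: the model sees assigned reads only.
    """
    if not state.valid:
        return -np.inf
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mean_x = state.mu * state.beta * (1.0 - state.q)
    mean_y = state.mu * state.alpha * state.beta * state.q
    lp = float(stats.poisson.logpmf(x, mean_x).sum()
               + stats.poisson.logpmf(y, mean_y).sum())
    for v in (state.mu, state.alpha, *state.beta):
        lp += float(stats.gamma.logpdf(v, a=_PRIOR_SHAPE, scale=1 / _PRIOR_RATE))
    return lp


class BaselineModel:
    """Poisson baseline for one condition of one unit.

    Parameters
    ----------
    x, y : arrays of int
        Maternal and paternal assigned counts per replicate.
    q : float
        Known expected paternal share of assigned reads under balance
        (0.5 when mapping is unbiased; r_p / (r_m + r_p) in terms of the
        assignment rates).
    """

    def __init__(self, x, y, q: float = 0.5):
        self.x = np.asarray(x, dtype=np.int64)
        self.y = np.asarray(y, dtype=np.int64)
        if self.x.size != self.y.size or self.x.size < 1:
            raise ValueError("x and y need equal length >= 1")
        if (self.x < 0).any() or (self.y < 0).any():
            raise ValueError("counts must be non-negative")
        if not 0 < q < 1:
            raise ValueError("q must lie in (0, 1)")
        self.q = float(q)

    def fit(self, settings: McmcSettings = McmcSettings(),
            level: float = 0.95) -> "BaselineResults":
        k = self.x.size
        init = np.zeros(2 + k)
        tot = np.maximum((self.x + self.y) / 2.0, 0.5)
        init[0] = np.log(tot.mean())          # mu
        init[2:] = np.log(tot / tot.mean())   # beta_k around 1
        draws, rates = _sampler.run_baseline_chain(
            self.x.astype(float), self.y.astype(float), self.q,
            _PRIOR_SHAPE, _PRIOR_RATE, init,
            settings.n_iter, settings.burn_in, settings.thin,
            int(settings.seed) % (2**32), settings.adapt,
            settings.target_accept,
        )
        alpha = draws[:, 1]
        lo, hi = np.quantile(alpha, [(1 - level) / 2, 1 - (1 - level) / 2])
        summary = ParamSummary(
            mean=float(alpha.mean()), median=float(np.median(alpha)),
            ci_low=float(lo), ci_high=float(hi),
            ess=effective_sample_size(alpha),
        )
        return BaselineResults(
            model=self, settings=settings, level=level,
            alpha_draws=alpha, mu_draws=draws[:, 0],
            beta_draws=draws[:, 2:], accept_rates=rates,
            alpha=summary, reject_ai=not summary.contains(1.0),
        )


@dataclass
class BaselineResults:
    """Posterior summary for the baseline imbalance parameter alpha."""

    model: BaselineModel
    settings: McmcSettings
    level: float
    alpha_draws: np.ndarray
    mu_draws: np.ndarray
    beta_draws: np.ndarray
    accept_rates: np.ndarray
    alpha: ParamSummary
    reject_ai: bool

    @property
    def theta(self) -> float:
        """Posterior-mean paternal-vs-maternal proportion alpha/(1+alpha)."""
        return float((self.alpha_draws / (1.0 + self.alpha_draws)).mean())

    def summary(self) -> str:
        a = self.alpha
        return (
            f"Poisson baseline (q={self.model.q:g}, "
            f"K={self.model.x.size}, draws={self.alpha_draws.size})\n"
            f"alpha: mean {a.mean:.4f}, median {a.median:.4f}, "
            f"{self.level:.0%} CI [{a.ci_low:.4f}, {a.ci_high:.4f}], "
            f"ess {a.ess:.0f}\n"
            f"AI ({self.level:.0%} CI excludes 1): "
            f"{'yes' if self.reject_ai else 'no'}"
        )


def run_baseline(x, y, q: float = 0.5,
                 settings: McmcSettings = McmcSettings(),
                 level: float = 0.95) -> BaselineResults:
    """Convenience wrapper: fit the baseline model to one condition."""
    return BaselineModel(x, y, q).fit(settings, level=level)


def descriptive_gxe(flag_env1: bool, flag_env2: bool) -> bool:
    """Descriptive imbalance-by-condition call: AI in exactly one condition."""
    return bool(flag_env1) != bool(flag_env2)
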