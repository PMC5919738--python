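"""Synthetic allele-specific count data and the type I/II error studies.

Counts are drawn per condition, replicate and count class from negative
binomials with size (inverse-dispersion) ``nb_size`` and the model's
expected values: expression scale ``beta_{i,k} * eta_i`` modulated by
the imbalance parameters ``alpha_i`` and a common assignment rate
``r_sim`` for both alleles. The unassigned expectation can be inflated
by a large factor to emulate nearly identical haplotypes, and the rates
handed to the *fitted* model can be deliberately misspecified to probe
robustness to imperfect bias estimates.

A scenario grid crossed over the log2 imbalance ratio, coverage,
misspecification and unassigned inflation reproduces the operating
characteristics of the credible-interval tests (type I error under
alpha1 = alpha2 = 1, power elsewhere), with the descriptive baseline
comparison fitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .baseline import descriptive_gxe, run_baseline
from .datatypes import AlleleCountSet, BiasSpec, McmcSettings
from .model import EnvironmentalModel, derive_unit_seed

__all__ = [
    "SimScenario",
    "ErrorTable",
    "alpha_grid",
    "misspecified_rate",
    "simulate_unit",
    "run_error_study",
]

#: replicate-level expression scales used throughout the simulation study
DEFAULT_BETA_TABLE = ((1.0, 1.2, 0.7), (1.0, 1.3, 0.8))


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation design.

    ``log2_ratio`` is log2(alpha1/alpha2); with ``alpha_1 = 1`` the grid
    value -1 puts alpha2 at 2 and +1 at 0.5. ``r_sim`` is the common
    assignment rate generating the data (slightly below 1 by default so
    unassigned reads exist); ``misspec_x`` is the bias misspecification
    in percent handed to the fitted model, ``x = 200 * (r_fit - r_sim)``.
    """

    n_units: int = 1000
    n_reps: int = 3
    beta_table: tuple[tuple[float, ...], tuple[float, ...]] = DEFAULT_BETA_TABLE
    eta_1: float = 100.0
    eta_2: float = 100.0
    nb_size: float = 50.0
    alpha_1: float = 1.0
    log2_ratio: float = 0.0
    r_sim: float = 0.98
    misspec_x: float = 0.0
    unassigned_inflation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta_table) != 2 or any(
                len(row) != self.n_reps for row in self.beta_table):
            raise ValueError("beta_table must be 2 x n_reps")
        for name in ("eta_1", "eta_2", "nb_size", "alpha_1", "r_sim",
                     "unassigned_inflation"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_units < 1 or self.n_reps < 1:
            raise ValueError("n_units and n_reps must be >= 1")

    @property
    def alpha_2(self) -> float:
        return self.alpha_1 / 2.0**self.log2_ratio

    @property
    def r_fit(self) -> float:
        """Assignment rate handed to the fitted model (possibly misspecified)."""
        return misspecified_rate(self.r_sim, self.misspec_x)


def alpha_grid() -> np.ndarray:
    """The 11 log2(alpha1/alpha2) levels of the study: -1 to 1, step 0.2."""
    return np.round(np.linspace(-1.0, 1.0, 11), 10)


def misspecified_rate(r_sim: float, x: float) -> float:
    """Assignment rate after misspecification of x percent: r + x/200.

    Values above 1 are passed through deliberately (the fitted model
    floors the resulting negative unassigned expectation).
    """
    if r_sim <= 0:
        raise ValueError("r_sim must be > 0")
    r_fit = r_sim + x / 200.0
    if r_fit <= 0:
        raise ValueError(f"misspecification x={x} drives the rate to {r_fit}")
    return r_fit


def _nb_draw(rng: np.random.Generator, mean: float, size_param: float,
             n: int) -> np.ndarray:
    """n draws from NB with given mean and size (var = mean + mean^2/size)."""
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n).astype(np.int64)


def simulate_unit(scn: SimScenario, unit_seed: int,
                  unit_id: str = "sim") -> AlleleCountSet:
    """Draw one unit's counts under the scenario's generating model.

    x, y and z are independent negative binomials per replicate with the
    model means at (alpha_i, beta_{i,k} * eta_i, r_sim); the unassigned
    mean is additionally multiplied by the scenario's inflation factor.
    """
    rng = np.random.default_rng(unit_seed)
    alphas = (scn.alpha_1, scn.alpha_2)
    etas = (scn.eta_1, scn.eta_2)
    x, y, z = [], [], []
    for i in range(2):
        a = alphas[i]
        scale = np.asarray(scn.beta_table[i]) * etas[i]
        xi = np.empty(scn.n_reps, dtype=np.int64)
        yi = np.empty(scn.n_reps, dtype=np.int64)
        zi = np.empty(scn.n_reps, dtype=np.int64)
        for k in range(scn.n_reps):
            mean_x = a * scale[k] * scn.r_sim
            mean_y = scale[k] * scn.r_sim / a
            mean_z = ((1.0 - scn.r_sim) / a + (1.0 - scn.r_sim) * a) \
                * scale[k] * scn.unassigned_inflation
            xi[k] = _nb_draw(rng, mean_x, scn.nb_size, 1)[0]
            yi[k] = _nb_draw(rng, mean_y, scn.nb_size, 1)[0]
            zi[k] = _nb_draw(rng, mean_z, scn.nb_size, 1)[0]
        x.append(xi)
        y.append(yi)
        z.append(zi)
    return AlleleCountSet(unit_id=unit_id, conditions=("env1", "env2"),
                          x=tuple(x), y=tuple(y), z=tuple(z))


@dataclass
class ErrorTable:
    """Rejection fractions per scenario cell, with Monte-Carlo SEs.

    ``table`` has one row per scenario; rejection-fraction columns are
    paired with ``se_*`` columns (SE = sqrt(p(1-p)/n_units)). ``h03`` is
    the formal credible-interval test of equal imbalance across
    conditions; ``env_desc`` and ``base_desc`` are the descriptive
    exactly-one-condition calls under the hierarchical and baseline
    models respectively.
    """

    table: pd.DataFrame
    per_unit: pd.DataFrame | None = None

    _FRACS = ("h01", "h02", "h03", "env_desc", "base_ai1", "base_ai2",
              "base_desc")

    def __post_init__(self) -> None:
        for c in self._FRACS:
            bad = (self.table[c] < 0) | (self.table[c] > 1)
            if bad.any():
                raise ValueError(f"rejection fraction {c} outside [0, 1]")


def _fit_one(unit: AlleleCountSet, scn: SimScenario, tag: str,
             settings: McmcSettings, fit_baseline: bool) -> dict[str, bool]:
    r_fit = scn.r_fit
    bias = BiasSpec.uniform(r_fit, allow_above_one=True)
    env = EnvironmentalModel(unit, bias).fit(
        replace(settings, seed=derive_unit_seed(scn.seed, f"{tag}:env")))
    s = env.posterior
    out = {
        "h01": s.reject_h01, "h02": s.reject_h02, "h03": s.reject_h03,
        "env_desc": descriptive_gxe(s.reject_h01, s.reject_h02),
        "low_ess": s.low_ess_warning,
    }
    if fit_baseline:
        q = 0.5  # r_fit applied to both alleles: r_p/(r_m + r_p)
        base = [
            run_baseline(
                unit.x[i], unit.y[i], q,
                replace(settings,
                        seed=derive_unit_seed(scn.seed, f"{tag}:b{i}")))
            for i in range(2)
        ]
        out.update({
            "base_ai1": base[0].reject_ai, "base_ai2": base[1].reject_ai,
            "base_desc": descriptive_gxe(base[0].reject_ai,
                                         base[1].reject_ai),
        })
    return out


def run_error_study(scenarios: Iterable[SimScenario],
                    settings: McmcSettings = McmcSettings(),
                    keep_units: bool = False,
                    fit_baseline: bool = True) -> ErrorTable:
    """Simulate and fit every scenario cell; tabulate rejection fractions.

    For each unit the hierarchical model is fitted with the (possibly
    misspecified) rates and, for the descriptive comparison, the Poisson
    baseline is fitted per condition. Per-unit fit warnings (low
    effective sample size) are counted, never fatal. Deterministic given
    each scenario's seed; unit-level seeds are derived from it, so
    results do not depend on execution order.
    """
    rows = []
    unit_rows = []
    for scn in scenarios:
        flags = []
        n_failed = 0
        for j in range(scn.n_units):
            tag = f"unit{j}"
            unit = simulate_unit(scn, derive_unit_seed(scn.seed, tag),
                                 unit_id=tag)
            try:
                res = _fit_one(unit, scn, tag, settings, fit_baseline)
            except ValueError:
                # e.g. degenerate empirical-Bayes input; count, keep going
                n_failed += 1
                continue
            flags.append(res)
            if keep_units:
                unit_rows.append({"unit": tag, "log2_ratio": scn.log2_ratio,
                                  "misspec_x": scn.misspec_x, **res})
        f = pd.DataFrame(flags)
        n = len(f)
        row = {
            "n_units": n, "n_failed": n_failed,
            "eta_1": scn.eta_1, "eta_2": scn.eta_2,
            "alpha_1": scn.alpha_1, "alpha_2": scn.alpha_2,
            "log2_ratio": scn.log2_ratio, "misspec_x": scn.misspec_x,
            "unassigned_inflation": scn.unassigned_inflation,
            "r_sim": scn.r_sim, "seed": scn.seed,
            "n_low_ess": int(f["low_ess"].sum()),
        }
        for c in ErrorTable._FRACS:
            if c not in f.columns:
                row[c] = np.nan
                row[f"se_{c}"] = np.nan
                continue
            p = float(f[c].mean())
            row[c] = p
            row[f"se_{c}"] = float(np.sqrt(p * (1.0 - p) / n))
        rows.append(row)
    return ErrorTable(table=pd.DataFrame(rows),
                      per_unit=pd.DataFrame(unit_rows) if keep_units else None)
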