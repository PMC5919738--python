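"""Core containers shared across the package.

The observational unit throughout is a genomic unit (an exon, or an
exon measured in one F1 line) with allele-specific read counts in two
conditions ("environments"): for condition ``i`` and biological
replicate ``k`` we observe ``x[i][k]`` reads assigned to the maternal
allele, ``y[i][k]`` reads assigned to the paternal allele and
``z[i][k]`` reads that aligned equally well to both haplotypes and
could not be assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "AlleleCountRecord",
    "AlleleCountSet",
    "BiasSpec",
    "QCConfig",
    "PriorConfig",
    "McmcSettings",
    "ParamSummary",
    "PosteriorSummary",
]


@dataclass(frozen=True)
class AlleleCountRecord:
    """One row of a count table: one replicate of one condition of one unit."""

    unit_id: str
    condition_id: str
    replicate_index: int
    x: int
    y: int
    z: int

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(
                    f"count {name}={v!r} for unit {self.unit_id!r} must be a "
                    "non-negative integer"
                )
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be a positive integer")


@dataclass
class AlleleCountSet:
    """Allele-specific counts for one unit in exactly two conditions.

    ``x``, ``y`` and ``z`` are pairs of integer arrays; element ``i`` holds
    the per-replicate counts for condition ``conditions[i]``. Replicate
    numbers ``K_1`` and ``K_2`` may differ.
    """

    unit_id: str
    conditions: tuple[str, str]
    x: tuple[np.ndarray, np.ndarray]
    y: tuple[np.ndarray, np.ndarray]
    z: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        self.x = tuple(np.asarray(a, dtype=np.int64) for a in self.x)
        self.y = tuple(np.asarray(a, dtype=np.int64) for a in self.y)
        self.z = tuple(np.asarray(a, dtype=np.int64) for a in self.z)
        for i in range(2):
            k = self.x[i].size
            if k < 1:
                raise ValueError(
                    f"unit {self.unit_id!r}: condition {self.conditions[i]!r} "
                    "has no replicates"
                )
            if self.y[i].size != k or self.z[i].size != k:
                raise ValueError(
                    f"unit {self.unit_id!r}: x, y, z replicate vectors differ "
                    "in length"
                )
            for arr in (self.x[i], self.y[i], self.z[i]):
                if (arr < 0).any():
                    raise ValueError(f"unit {self.unit_id!r}: negative count")

    @property
    def n_reps(self) -> tuple[int, int]:
        return (self.x[0].size, self.x[1].size)

    def assigned_sum(self, i: int) -> int:
        """Total assigned reads (x + y) in condition ``i``, summed over replicates."""
        return int(self.x[i].sum() + self.y[i].sum())

    def total_reads(self) -> int:
        return int(sum(a.sum() for t in (self.x, self.y, self.z) for a in t))

    def assigned_fraction(self, i: int | None = None) -> float:
        """Fraction of reads assigned to either allele, pooled or per condition."""
        if i is None:
            tot = self.total_reads()
            asg = self.assigned_sum(0) + self.assigned_sum(1)
        else:
            tot = int(self.x[i].sum() + self.y[i].sum() + self.z[i].sum())
            asg = self.assigned_sum(i)
        return asg / tot if tot > 0 else 0.0

    def swapped_labels(self) -> "AlleleCountSet":
        """Return a copy with maternal and paternal assignments exchanged."""
        return AlleleCountSet(
            unit_id=self.unit_id,
            conditions=self.conditions,
            x=tuple(a.copy() for a in self.y),
            y=tuple(a.copy() for a in self.x),
            z=tuple(a.copy() for a in self.z),
        )


@dataclass(frozen=True)
class BiasSpec:
    """Allele-assignment probabilities per condition.

    ``r_m[i]`` (``r_p[i]``) is the probability that a read truly generated
    by the maternal (paternal) haplotype is assigned to it in condition
    ``i``; the complement is left unassigned. Values above 1 are physically
    impossible and only accepted when ``allow_above_one`` is set, which the
    bias-misspecification harness uses to probe model robustness.
    """

    r_m: tuple[float, float]
    r_p: tuple[float, float]
    allow_above_one: bool = False

    def __post_init__(self) -> None:
        for name, pair in (("r_m", self.r_m), ("r_p", self.r_p)):
            for v in pair:
                if not v > 0:
                    raise ValueError(f"{name} must be strictly positive, got {v}")
                if v > 1 and not self.allow_above_one:
                    raise ValueError(
                        f"{name}={v} exceeds 1; pass allow_above_one=True to "
                        "use a deliberately misspecified rate"
                    )

    def swapped_labels(self) -> "BiasSpec":
        return BiasSpec(r_m=self.r_p, r_p=self.r_m,
                        allow_above_one=self.allow_above_one)

    @classmethod
    def uniform(cls, r: float, allow_above_one: bool = False) -> "BiasSpec":
        return cls(r_m=(r, r), r_p=(r, r), allow_above_one=allow_above_one)


@dataclass(frozen=True)
class QCConfig:
    """Quality-control thresholds applied to each unit before fitting.

    A unit is kept when the assigned reads (x + y, summed over replicates)
    reach ``min_assigned_reads`` in *both* conditions, the grand total of
    reads (assigned or not) reaches ``min_total_reads``, and the fraction
    of reads assigned to either allele reaches ``min_assigned_fraction``
    (pooled over the unit by default; set ``fraction_per_condition`` to
    require it in each condition separately).
    """

    min_assigned_reads: int = 50
    min_total_reads: int = 200
    min_assigned_fraction: float = 0.01
    fraction_per_condition: bool = False

    def __post_init__(self) -> None:
        if min(self.min_assigned_reads, self.min_total_reads) < 0:
            raise ValueError("read thresholds must be >= 0")
        if self.min_assigned_fraction < 0:
            raise ValueError("min_assigned_fraction must be >= 0")


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the hierarchical negative-binomial model.

    * ``alpha_i ~ lognormal(mu_alpha, sigma2_alpha)`` — symmetric in the
      maternal/paternal labels; the default sd 1/4 keeps the prior mean of
      alpha at exp(1/32) ≈ 1.03 so uninformative data do not suggest
      imbalance.
    * ``beta_{i,k} ~ gamma(a_beta, b_beta)`` with
      ``b_beta ~ gamma(a_bbeta, b_bbeta)`` — the hyperprior pools the
      replicate-level expression scales; ``a_beta`` and the hyperprior are
      set from the data by :func:`aibayes.model.empirical_hyperparams`.
    * ``phi ~ inverse-gamma(a_phi, b_phi)`` — the common NB dispersion
      (variance = mean + phi * mean**2); the default (2.01, 0.05) is an
      informative prior with mean ≈ 0.05.
    """

    mu_alpha: float = 0.0
    sigma2_alpha: float = 1.0 / 16.0
    a_phi: float = 2.01
    b_phi: float = 0.05
    a_beta: float | None = None
    a_bbeta: float | None = None
    b_bbeta: float | None = None

    def __post_init__(self) -> None:
        if self.sigma2_alpha <= 0:
            raise ValueError("sigma2_alpha must be > 0")
        for name in ("a_phi", "b_phi", "a_beta", "a_bbeta", "b_bbeta"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @property
    def complete(self) -> bool:
        return None not in (self.a_beta, self.a_bbeta, self.b_bbeta)

    def with_beta_hyperparams(self, a_beta: float, a_bbeta: float,
                              b_bbeta: float) -> "PriorConfig":
        return replace(self, a_beta=a_beta, a_bbeta=a_bbeta, b_bbeta=b_bbeta)


@dataclass(frozen=True)
class McmcSettings:
    """Settings for the adaptive random-walk Metropolis-within-Gibbs sampler."""

    n_iter: int = 12000
    burn_in: int = 4000
    thin: int = 1
    seed: int = 0
    adapt: bool = True
    target_accept: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass(frozen=True)
class ParamSummary:
    """Posterior mean, median, equal-tailed credible interval and ESS."""

    mean: float
    median: float
    ci_low: float
    ci_high: float
    ess: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValueError("require ci_low <= median <= ci_high")

    def contains(self, value: float) -> bool:
        """Closed-interval containment (an interval touching value includes it)."""
        return self.ci_low <= value <= self.ci_high


# parameters reported for every unit, in output order
SUMMARY_PARAMS = ("alpha1", "alpha2", "alpha_ratio", "theta1", "theta2")


@dataclass
class PosteriorSummary:
    """Per-unit posterior summary and the three credible-interval tests.

    ``reject_h01`` / ``reject_h02`` flag allelic imbalance within condition
    1 / 2 (the CI for alpha_i excludes 1); ``reject_h03`` flags a change of
    imbalance across conditions (the CI for alpha1/alpha2 excludes 1) —
    the G-by-E test.
    """

    unit_id: str
    level: float
    alpha1: ParamSummary
    alpha2: ParamSummary
    alpha_ratio: ParamSummary
    theta1: ParamSummary
    theta2: ParamSummary
    reject_h01: bool = field(default=False)
    reject_h02: bool = field(default=False)
    reject_h03: bool = field(default=False)
    low_ess_warning: bool = field(default=False)

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2"):
            p: ParamSummary = getattr(self, name)
            if not (0.0 < p.mean < 1.0):
                raise ValueError(f"{name} estimates must lie in (0, 1)")
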