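# Methods

## Model

Each analysis unit (an exon, or an exon within one F1 line) contributes
three counts per condition *i* and replicate *k*: maternal-assigned
x_{i,k}, paternal-assigned y_{i,k}, unassigned z_{i,k}. Conditional on
the parameters these are independent negative binomials with common
dispersion φ (variance μ + φμ²) and means α_i β_{i,k} r_{i,m},
(1/α_i) β_{i,k} r_{i,p} and [(1−r_{i,p})/α_i + (1−r_{i,m}) α_i] β_{i,k}.
The three means sum to β_{i,k}(α_i + 1/α_i), so the total read count of
a replicate is itself random with expectation proportional to β_{i,k}:
library sampling variance is part of the model rather than conditioned
away, and the unassigned class — which carries no allelic information —
still informs expression level and dispersion. α_i² is the
bias-corrected maternal/paternal mean ratio and
θ_i = α_i²/(α_i²+1) ∈ (0,1) the maternal expression proportion.

Assignment rates r (probability that a read from a haplotype is
assigned to it) are supplied per unit and condition, from the built-in
enumeration estimator or externally (DNA controls). They are kept
separate per condition and per parent: haplotype reference quality need
not be symmetric.

## Priors and empirical Bayes

* α_i ~ lognormal(μ=0, σ²=1/4²). Symmetric in the maternal/paternal
  labels (α and 1/α are exchangeable a priori) with prior mean
  exp(1/32) ≈ 1.03. This prior is deliberately informative: with
  noninformative data the posterior reproduces it and no imbalance is
  concluded. The flip side, verified numerically, is that for extreme
  imbalance (α ≳ 5–10) combined with a free dispersion the posterior
  can genuinely prefer a compromise mode with moderate α and inflated
  φ; within the simulation study's range (α ∈ [0.5, 2]) this never
  binds.
* β_{i,k} ~ gamma(a_β, b_β), b_β ~ gamma(a_{bβ}, b_{bβ}). Set by
  empirical Bayes: rough scales β̂_{i,k} = (x+y+z)_{i,k}/2 (exact at
  balance with full assignment, since E total = β(α+1/α) = 2β; floored
  at 0.5), a gamma ML fit (â, b̂) to them, then a_β = â,
  a_{bβ} = 2 b̂, b_{bβ} = 2 so that E(b_β) = b̂. The hyperprior on the
  rate rather than a fixed rate lets replicates pool strength.
* φ ~ inverse-gamma(2.01, 0.05), an informative prior with mean ≈ 0.05
  (few counts inform a per-unit dispersion).

The gamma ML solves the profile score equation
log a − ψ(a) = log(mean) − mean(log) with a Minka-type start; constant
input (zero spread) is an error, which study drivers catch per unit.

## Sampling and decisions

Adaptive random-walk Metropolis-within-Gibbs on the log scale, one site
at a time: log α₁, log α₂, each log β_{i,k}, log b_β, log φ. Step sizes
adapt in batches of 50 iterations during burn-in toward 30% acceptance
(Robbins–Monro increments capped at 0.05), then freeze. Defaults:
12000 iterations, 4000 burn-in, thin 1 → 8000 draws, ~0.2 s per unit
(numba-compiled kernels; the first call pays a few seconds of JIT).
The chains are bit-reproducible given the seed; per-unit seeds are
derived as SHA-256(master seed, unit id) mod 2³¹ so results are
independent of execution order.

α₁ starts at its empirical estimate √[(Σx/r_m)/(Σy/r_p)] (clipped to
[0.02, 50]), β at total/(α̂+1/α̂): starting at α = 1 can strand the
chain in the inflated-dispersion mode described above.

Equal-tailed credible intervals come from sample quantiles; α₁/α₂ and
θ_i are computed samplewise. H01/H02/H03 are rejected when the
closed interval for α₁, α₂, α₁/α₂ respectively excludes 1 (an interval
touching 1 does not reject). Effective sample size uses Geyer's initial
monotone positive-sequence estimator; ESS < 100 for the ratio sets a
warning flag on the summary, never an exception.

Degenerate means: with r = 1 the unassigned mean is exactly 0 and the z
likelihood is a point mass at zero (observed z > 0 then has zero
probability — such states are rejected with −∞, not raised). Rates
above 1 are admitted only in the misspecification harness; the then
negative unassigned bracket is floored at 1e−8 to keep the likelihood
proper.

## Baseline comparator

The single-condition Poisson model: x_k ~ Poisson(μ β_k (1−q)),
y_k ~ Poisson(μ α β_k q) with gamma(1/2, 1/2) priors on μ, α and each
β_k, and q a fixed known constant (r_p/(r_m+r_p) under the null;
0.5 for symmetric bias). Unassigned reads never enter. Across two
conditions it supports only the descriptive interaction call: AI
flagged in exactly one condition (XOR). Note the gamma priors are not
reciprocal-symmetric, so the baseline's α posterior carries a small
label-dependent tilt — one of the asymmetries the hierarchical model's
lognormal priors remove.

## Synthetic data

The simulator reproduces the study design: counts drawn independently
per class, replicate and condition from NB(size 50) at the model means,
with replicate scales ((1, 1.2, 0.7), (1, 1.3, 0.8)), expression
factor η ∈ {10, 100} (possibly unequal between conditions), α₁ = 1 and
α₂ = 2^(−log2ratio) over the 11-point grid −1 … 1 step 0.2, an
unassigned inflation factor ∈ {1, 10000} emulating nearly identical
haplotypes, and bias misspecification x = 200·(r_fit − r_sim) percent
applied symmetrically to the rates handed to the fitted model.

The generating rate defaults to r_sim = 0.98 rather than 1: with
r_sim = 1 the expected unassigned count is identically zero, which
would make the inflation factor inert and the misspecification anchor
ill-defined; a small positive unassignment keeps every scenario axis
meaningful (r_sim = 1 remains available). What the generator does not
emulate: correlated x/y/z draws within a replicate, per-unit bias
heterogeneity, exon-length and GC effects, or real aligner behavior
(indels, paralogs) — passing tests demonstrate correct operating
characteristics under the model's own sampling assumptions, not
robustness to those real-data features.

Study drivers tabulate rejection fractions for H01/H02/H03, the
descriptive calls under both models, and binomial standard errors
√(p(1−p)/n); per-unit failures (e.g. degenerate empirical-Bayes input)
are counted, never fatal.

## Bias estimation

For equal-length, SNP-substituted haplotype pairs, every read of length
L from every start position is classified by positional Hamming
comparison over its window of origin: strictly fewer mismatches assigns
the read, ties are unassigned, N bases are ignored on both sides. The
assigned fraction per haplotype is (r_m, r_p). A single SNP at distance
≥ L from both ends is overlapped by L of the N−L+1 windows, giving
r = L/(N−L+1). Gapped alignment and sequencing error are out of scope;
externally measured rates can be supplied via the bias TSV instead.

## Quality control

A unit is analysed when (1) the fraction of reads assigned to either
allele is ≥ 1% (pooled over the unit by default; per-condition behind a
switch), (2) assigned reads reach 50 in each condition, and
(3) total reads reach 200 over the whole unit. The first failing rule
in that order is reported. Thresholds are configurable.

## Population statistics

Per-exon excess/depletion of interaction calls across lines uses
one-sided Fisher exact tests of the exon's (changed, unchanged) line
counts against all other exons' pooled data points (raw p-values;
Benjamini–Hochberg is available as clearly optional extra output; a
switch restricts the background to the exon's own lines). Model
agreement uses Cohen's κ from 2×2 confusion matrices; imbalance
categories are "both balanced / one / both imbalanced", and a gene is
flagged when any exon in any line is.

## Study sizes and numerical choices

The packaged acceptance checks run the type-I study at 100 units per
misspecification cell, calibration at 200 units, power at 50 units per
cell and the unequal-coverage comparison at 100 units — sizes at which
binomial standard errors (reported throughout) make the claimed
contrasts decisive while a full check stays in the minutes range; the
scenario default is 1000 units per cell and the drivers accept any
size. The reduced-model oracle check integrates the exact
single-condition posterior on a 2001-point log-α grid over ±3 log
units. Tolerances: grid-vs-MCMC agreement 0.02 absolute on the
posterior mean and 95% CI endpoints of α₁; Fisher/bias oracle
agreement 1e−12; KS < 0.05 for label-swap symmetry of the hierarchical
model.

## Known limitations

Two conditions only (the design the model defines); no variational or
exact-integration production path; the baseline's fixed q ignores
DNA-control uncertainty; per-unit fitting treats units independently
(no sharing across exons); credible-interval decisions are not
multiplicity-adjusted, matching the procedure the statistics summarize.
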