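# Methods

## Model

Four cohorts are sampled: discovery controls `C0` (n0 individuals) and cases
`C1` (n1), replication controls `C0'` (n0p) and cases `C1'` (n1p).  For one
biallelic variant, each cohort's minor-allele count is modelled as
`Binomial(2n, μ)` (diploid, Hardy–Weinberg, allele-level sampling), so a
cohort frequency estimator has variance `μ(1-μ)/(2n)`.  Five signed
score-type Z-statistics are formed from differences of cohort (or
count-weighted pooled) frequency estimators over their pooled-null standard
errors:

| statistic | comparison |
|---|---|
| `z_d` | `C1` vs `C0` |
| `z_r` | `C1'` vs `C0'` |
| `z_s` | `C1'` vs `C0 ∪ C0'` |
| `z_c` | `C1` vs `C0 ∪ C0'` |
| `z_m` | `C1 ∪ C1'` vs `C0 ∪ C0'` |

Method A declares a hit when `p_d < α`, `p_r < β`, `p_m < γ` with all three
effects in the same direction; method B replaces `(p_r, β)` by `(p_s, β*)`;
method C uses `(p_c, α)` and `(p_s, β⊥)`.  All p-value thresholds are
two-sided and map to the z-scale as `z_x = -Φ⁻¹(x/2)`.

### Null correlation structure

Under the global null all five Z's are jointly Gaussian with unit variance.
Writing `u_X` for the reciprocal cohort size and `u_00 = 1/(n0+n0p)`,
`u_11 = 1/(n1+n1p)` for the pooled groups, the covariance contributed by
shared cohorts gives closed forms such as

    ρ_ds = u_00 / sqrt((u_1+u_0)(u_1p+u_00)),
    ρ_dm = sqrt(u_11+u_00) / sqrt(u_1+u_0),    ρ_dr = 0.

These are *derived from first principles* rather than transcribed from any
single published table: the derivation reproduces the classical sample-size
formula for `ρ_ds` exactly and is confirmed against binomial simulation for
all seven pairs (several historically printed variants of `ρ_dm`, `ρ_rm`
and `ρ_cs` are mutually inconsistent — e.g. yield values above 1, or 2/3 for
a fully balanced design where inverse-variance weighting forces `1/√2` —
and are not used).  The correlations depend only on the four cohort sizes,
and are invariant under common rescaling of the counts.

`Σ_C` (for `(z_c, z_s, z_m)`) is singular for every design: the meta
statistic is an exact linear combination of the other two.  `Σ_A` and `Σ_B`
are singular precisely when `n0/n1 = n0'/n1'`.  A matrix is routed to the
rank-2 integration path when its smallest eigenvalue is below `1e-9` of the
largest, or its condition number exceeds `1e8`; the linear coefficients come
from regressing the third coordinate on the first two.

### Tail-probability engine

Every output is a shifted-orthant probability `Pr(Z_i > l_i)` of a 2- or
3-dimensional zero-mean Gaussian.  The probabilities involved span ~0.5 down
to ~1e-18, so the kernel is fully deterministic nested Gauss–Legendre
quadrature (no Monte-Carlo, no randomised lattice rules): an outer integral
over the first coordinate with the conditional bivariate upper tail inside.
The bivariate tail is itself a 1-D integral of `φ·Φ̄`; for conditional
correlation |r| > 0.925 that integrand develops an arbitrarily steep step,
so the kernel switches to Plackett's identity (`dP/dr` equals the bivariate
density), integrating the density over the correlation parameter with a
`t = sin θ` substitution that removes the endpoint singularity.  Rank-2
matrices are integrated over the two free coordinates with the half-plane
constraint clipped against the rectangle; the crossing point is made a panel
boundary so the integrand stays smooth per panel.

Numerical choices: composite Gauss–Legendre with ~22 panels of 16 nodes;
lower limits clipped at −8.6 (absolute error below `Φ(-8.6) ≈ 4e-18`, active
only when the probability is large); upper truncation 13 units past the
largest bound (relative error `≲ e^{-13 z}` in deep tails).  Full-rank
accuracy is ~1e-12 relative; the rank-2 and ridge-perturbed full-rank paths
agree to better than 1e-6.

### Adjusted thresholds

`β*` and `β⊥` solve `NullRate_method(threshold) = P0` where
`P0 = 2·Pr(z_d > z_α, z_r > z_β, z_m > z_γ)` is method A's null hit rate
(the factor 2 counts the two consistent sign patterns).  The solver brackets
the z-scale threshold between `max(z_β, √(1-ρ²) z_β + ρ z_α)` — the
large-`z_α` asymptote, which the exact solution approaches from above — and
`z_β + |ρ| z_α + 6`, then runs Brent's method to a probability residual
below 1e-12 (in practice ~1e-15 relative).  `β⊥ < β* < β` holds on every
solvable input.

When no meta threshold is used (`γ = 1`) two conventions exist and both are
implemented.  The package default keeps the directional three-statistic rule
with `z_γ = 0`.  The alternative, exposed behind an explicit
`convention="nondirectional"` flag, conserves the two-sided pair rate
`Pr(|z_d| > z_α, |z_s| > z_{β*}) = αβ`; the two differ by the sign
constraint (the independent-case directional rate is `αβ/2`), and are *not*
interchangeable for correlated designs.

### Effects, misascertainment, aberrance

A variant's noncentrality vector `ζ = E[z]` follows the first-order
expansion `ζ = sqrt(2 n_eff) · Δμ / sqrt(μ̄(1-μ̄))`, with `n_eff` the usual
two-group effective size (pooled groups at combined size) and `μ̄` a single
count-weighted mean frequency over all four cohorts used in every
denominator — one consistent value keeps ζ ratios exactly equal to their
closed forms, e.g. `ζ_s/ζ_r = k = sqrt((n0+n0')(n0'+n1')/(n0'(n0+n0'+n1')))`
for replication-case aberrance.  Effects are specified as a (log-OR,
mean-MAF) pair solved to machine precision for `(μ0, μ1)` with the mean
constraint weighted by the discovery cohort sizes.  Misascertainment of
replication controls replaces `μ0'` by `(1-κ)μ0 + κμ1`.  Aberrance
(confounding that shifts a cohort's expected frequency) is parameterised on
the frequency scale through the same linear map; a ζ-scale entry point
(`scenario_zeta`) supports limit studies at arbitrarily large |ζ| where a
frequency offset would leave (0, 1).

Power at log-odds-ratio x is the sum of two shifted orthant probabilities
(positive- and negative-direction hit regions) under the method's *null*
covariance.  The average power difference is reported as the raw integral
over log-OR (Simpson on a 241-point grid inside a window grown until both
powers exceed 1-1e-6 at its ends) and additionally as the windowed mean,
since a percent-style normalisation of the integral is not canonical.  The
maximum difference uses a 401-point scan refined by golden-section.
Controls-for-parity is an integer bisection over added method-A replication
controls, with the variant's frequency spec anchored to the original design.

## Synthetic-data generator

`simulate_counts` draws independent binomial allele counts per cohort and
replicate — the minimal law consistent with the variance model above — and
`statistics_from_counts` applies exactly the score tests the analytics
model.  It emulates: sampling noise at finite cohort size, winner's-curse
selection bias (conditioning on `p_d < α` biases the shared replication
statistic, which the β→β* adjustment corrects), threshold/sign hit rules,
and frequency-shift confounding.  It does **not** emulate linkage
disequilibrium between variants, genotype-level covariate/strata adjustment,
platform or imputation error, or population stratification; passing tests
therefore validate the statistical calculus, not robustness to those
real-data features (the empirical-correlation estimator accepts a
user-supplied null Z table precisely so adjusted analyses can be calibrated
from their own data).

The Gaussian calculus is first-order in the frequency difference: at large
effects (|ζ| ≳ 5 with δ/μ̄ ≳ 0.1) the true binomial power deviates from the
analytic value by a few tenths of a percentage point (the score statistic's
variance is not exactly 1 under the alternative).  Monte-Carlo validation of
power and error rates is therefore run in the weak-effect / large-cohort
regime the expansion models; correlation validation has no such caveat.
Simulation sizes used by the test suite: 1e5–4e5 replicates, which resolve
rates to ~0.15% and correlations to ~0.2%.

## Design choices and limitations

* Counts are individuals; allele-level computations use 2n throughout.
* Probabilities are returned in [0, 1]; percentages appear only in prose.
* Method C's meta statistic pools the controls once (`C0 ∪ C0'` on both
  sides of its hit rule), and its replication threshold is always solved
  through the rank-2 path.
* The typical power ordering `Power_C ≥ Power_B ≥ Power_A` is just that —
  typical.  It can reverse at small replication cohorts or control-poor
  discovery; the test suite asserts it only on the favourable regime and as
  a majority property elsewhere.
* Strata/covariate-adjusted analytic correlations are out of scope; the
  supported path for adjusted statistics is empirical estimation (null-SNP
  sample correlations, or simulated genotypes processed by the user's own
  pipeline).
* Thresholds are taken as given; multiple-testing calibration across SNPs,
  cost models and decision-theoretic threshold optimisation are not
  addressed.
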