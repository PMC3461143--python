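# Methods

This note records the models implemented, the defaults chosen where the
original study left quantities unpublished, the numerical decisions, and the
limits of what the synthetic-data tests demonstrate.

## Removal census

Three-pass removal catches are modelled as a multinomial over capture
histories: pass `i` has probability `p q^{i-1}` (`q = 1 - p`), never-caught
`q^k`. The estimator profiles the log-likelihood over `p`, substituting the
closed-form abundance `N(p) = T / (1 - q^k)` (`T` total catch), solves by
bounded one-dimensional search (tolerance 1e-8 on `p`), and then polishes by
hill-climbing the exact integer-abundance profile with the conditional ML
capture probability `p(N) = T / (T + X + k(N - T))`, `X = Σ(i-1)c_i`. The
polish matters only for tiny catches, where continuous (Stirling) and
integer maxima can differ by about one fish; after it, the estimate equals
exhaustive integer-grid maximisation on every catch vector we scan.

When `X/T ≥ (k-1)/2` the catches carry no depletion signal: the profile
likelihood is then flat — within one log-unit of its `N → ∞` plateau, which
is the iid-Poisson(`T/k`) likelihood — and occasionally has a shallow
interior bump that is a discreteness artifact, not abundance information.
Such vectors are reported non-converged with abundance set to the total
catch.

## Seasonal effective number of breeders

Per sex, `Nb = N k̄ / (1 + V_k/k̄)` with `k̄`, `V_k` the sample mean and
variance (denominator n-1) of assigned offspring per spawner, zeros included
for spawners assigned none. The Crow–Denniston form
`(N k̄ - 1)/(k̄ - 1 + V_k/k̄)` is available behind `method="crow_denniston"`;
the ratio form is the default because it is the one consistent with the
reference seasonal tabulations this package reproduces. Two-sex combination
is harmonic, `4ab/(a+b)`, applied equally to census counts (sex-ratio effect
alone) and to per-sex effective numbers.

Bootstrap confidence intervals resample spawners with replacement within
sex, 1000 replicates by default, percentile bounds at 2.5/97.5%. A replicate
in which one sex draws an all-zero sample contributes a combined Nb of 0
(logged); at realistic zero fractions (>50% of spawners unassigned) this is
rare but must not crash. On synthetic data with moderate overdispersion the
nominal 95% interval covers the true combined Nb in ≥ 90% of datasets; with
the most extreme variance-to-mean ratios the percentile method is expected
to undercover somewhat, as for any variance-driven statistic on heavy tails.

## Stage-wise variance diagnostics

`R = V_k/k̄` per offspring age class; scaling to replacement mean family
size 2 under random binomial survival multiplies the excess index by the
survival fraction, giving `R* = 1 + (2/k̄)(R - 1)` and `Nb/N = 2/(1 + R*)`.
The scaling is applied as-is when `k̄ < 2` (it remains valid as an
inbreeding-effective-size equivalent); `R* < 0` (possible for `R < 1`,
`k̄ < 2`) is flagged inadmissible. The percent stage change is computed from
the scaled ratios, matching the reference column convention.

A caution on reproducing printed tables from printed inputs: with one-decimal
moments, cells with small mean family size are ill-conditioned — a rounding
shift of 0.05 in a mean of 0.4 moves `R*` by ~10%. The well-conditioned
cells reproduce to within 3%; the small-`k̄` cells only to within the input
rounding bound (~12%), and the published values were evidently computed from
unrounded moments.

## Lifetime simulation and per-generation Ne

Individuals enter at age 3 and are followed to age 8 (all assigned parents
in the motivating system fell in this range). Per age: maturation draw
(absorbing — a surviving mature fish spawns every season, consistent with
the observed repeat-spawning pattern), a seasonal offspring draw for mature
fish, then survival. Semelparous mode kills an individual after its first
mature season's reproduction, so it reproduces exactly once. All randomness
is drawn unconditionally in a fixed order, making the two modes exactly
coupled under a shared seed (iteroparous lifetime counts dominate
semelparous counts individual by individual).

Per replicate (default 1000 replicates of a 98-male, 108-female cohort) the
per-sex lifetime mean and variance, the offspring-weighted generation length
(spawning age + 1) and Hill's `Ne_V = 4NL/(2 + σ²_m + σ²_f)` are recorded.
`N` defaults to the cohort size (206); the seasonal census average of the
motivating system (196) can be configured instead — its own text uses 196
while also quoting cohort sizes summing to 206 and a census average of 209,
so the choice is exposed rather than hidden. Plugging that study's published
generation length (6.2), seasonal spawner average (196) and lifetime
variances (82.6, 22.7) into the formula yields 45.3, which does not
reproduce its published simulation-based estimate of 104.3 ± 44.9; the
exact quantities entering that figure are not recoverable from what was
published, so this package implements the formula as stated and makes no
attempt to match the number.

### Defaults chosen here (not published values)

* **Maturation curve**: observed proportions mature at ages 3–8 of
  0.10/0.30/0.60/0.85/0.95/1.0, giving a mean spawner age near 6 years as
  observed in the motivating system; the study's own curve was in
  unpublished supplementary material.
* **Survival schedule**: flat 0.5/year, a deliberate placeholder — the
  study's age-specific capture–recapture estimates were cited but not
  printed. Users with real schedules should supply them.
* **Seasonal fecundity**: per sex, a zero-inflated negative binomial
  matched to the three-season average family-size moments (males k̄ = 3.5,
  V = 74.5; females k̄ = 2.0, V = 14.1) with zero mass set to the observed
  fraction of spawners assigned no offspring (117/195 males, 140/256
  females), identical across ages. Empirical per-(sex, age) count vectors
  can be substituted.
* Within-individual draws are independent across years (no persistent
  individual quality); nothing published constrains this.

### Ageing errors

Scale-read ages of fish ≥ 3 years are underestimated by 1 year in 35% and
2 years in 18% of cases. The maturation-curve bootstrap re-ages exactly
those quotas, selected without replacement among eligible fish, 1000 times;
the induced mean age shift is 0.35 + 2·0.18 = 0.71 years. Re-aged fish
exceeding the curve's top age are pooled into the top age class for curve
fitting. Proportion-mature vectors with gaps carry the last observed value
forward and are monotonized (running maximum, with a warning); a vector
that reaches 1 and later drops is rejected as inconsistent.

### Sensitivity scans and the two Ne summaries

Fecundity variance is rescaled through the negative-binomial dispersion
(mean preserved exactly, counts remain non-negative); survival is rescaled
with clamping at 1. Each grid point reuses the base seed.

Two summaries are reported per point. `ne_v_mean` is the mean (with SD) of
the per-replicate `Ne_V`. `ne_v_plugin` applies Hill's formula to the
replicate-mean variances and generation length. At extreme variance
multipliers (5–10× a baseline that is already `V ≈ 20 k̄`) the lifetime
distribution becomes so heavy-tailed that a 206-fish cohort's variance
estimate fluctuates enormously between replicates, and because `Ne_V` is
convex in the variance, the mean of per-replicate values is inflated — to
the point of rising again between multipliers 5 and 10. This is a property
of the mean-of-ratios summary, not of the population quantity; trends
should be read from `ne_v_plugin`, which decreases monotonically in the
variance multiplier as the formula dictates.

On the survival axis the scan is strongly regime-dependent: doubling the
flat 0.5/year placeholder clamps to survival 1.0 — no mortality through age
8 — which multiplies lifetime-variance roughly five-fold and moves `Ne_V`
over a relative range comparable to the variance axis. The motivating
study reported near-insensitivity to survival; that behaviour evidently
depends on its unpublished age-specific schedule and empirical fecundity
structure and is not a generic property of this class of model. The
corresponding acceptance check is left failing rather than weakened, and
users should treat survival sensitivity as configuration-specific.

## What the synthetic data do and do not show

The generator reproduces the statistical skeleton the estimators assume:
configurable sex ratio and age structure, geometric repeat-spawning
persistence (fraction of spawners seen in >1 season equals the repeat
rate), zero-inflated overdispersed family sizes matched in mean/variance/
zero mass, family-correlated juvenile survival via beta-distributed
per-family survival (correlation 0 = random binomial thinning), ageing
error corruption, and binomial removal sampling. It does not emulate:
parentage-assignment error, unsampled immigrant parents, year effects or
density dependence in fecundity, length–fecundity covariance (lengths are
decorative), or genetic data of any kind. Passing parameter-recovery tests
therefore demonstrates estimator correctness under the assumed sampling
model, not robustness to those field realities.

## Problem sizes and runtimes

Default study sizes: three seasons of 98 + 108 spawners; 1000 bootstrap
replicates for Nb intervals; 1000 lifetime replicates (the acceptance
property checks use 400, and 400 per sensitivity grid point over the
5 × 3 multiplier grid). The exhaustive removal-estimator check scans all
~39,000 three-pass catch vectors with total ≤ 60 against the integer-grid
oracle. The full test suite runs in well under a minute on one core.

## Known limitations

* Demographic only: no temporal/linkage-disequilibrium genetic estimators.
* The per-generation machinery quantifies mechanisms; its absolute numbers
  inherit whatever fecundity and survival schedules are configured.
* The removal estimator assumes equal catchability across passes and
  individuals; heterogeneity biases abundance downward.
* Percentile bootstrap intervals undercover for extremely heavy-tailed
  family-size distributions.
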