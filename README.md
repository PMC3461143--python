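# ebreeders

Demographic estimation of effective population size for iteroparous,
age-structured stream salmonids — per-season effective numbers of breeders
from parentage-derived family sizes, removal-census abundance, family-size
variance diagnostics across juvenile stages, and an individual-based
lifetime-reproductive-success simulator yielding per-generation Ne.

The package is aimed at population and conservation geneticists working with
small, exhaustively sampled populations (the motivating system is a
stream-resident brown trout population monitored over consecutive spawning
seasons), where the ratio of effective to census size — and which life-history
factors depress it — is the management-relevant quantity.

## The estimators

**Census abundance.** Per season and sex, spawner numbers are estimated from
three-pass electrofishing removal catches by the Zippin maximum-likelihood
depletion method: catches `(c_1, ..., c_k)` are multinomial with cell
probabilities `p q^{i-1}` (and `q^k` for fish never caught), profiled over
the capture probability with an exact integer polish. Non-declining catches
have no finite ML and are flagged.

**Seasonal effective number of breeders.** With `N` spawners of one sex,
mean family size `k̄` (assigned offspring per spawner, zeros included) and
variance `V_k`:

    Nb_sex = N k̄ / (1 + V_k / k̄),        Nb = 4 Nb_m Nb_f / (Nb_m + Nb_f)

The harmonic two-sex combination is also applied to raw census counts to
isolate the sex-ratio effect. Uncertainty comes from a percentile bootstrap
resampling spawners with replacement within sex.

**Family-correlated survival.** For offspring counted at the age-1 and age-3
stages, the index of variability `R = V_k / k̄` is scaled to its expected
value at replacement mean family size 2 under random survival,
`R* = 1 + (2/k̄)(R - 1)`, giving `Nb/N = 2 / (1 + R*)`. If survival between
stages is random with respect to family, `R*` is unchanged in expectation;
an increase indicates family-concentrated mortality.

**Per-generation Ne.** A cohort of males and females is followed through the
reproductive ages (3–8), with an age-specific maturation curve
`m(a) = (o(a) - o(a-1)) / (1 - o(a-1))` inverted from proportions mature at
age (with a quota bootstrap for scale-reading ageing errors), an annual
survival schedule, and sex-specific seasonal fecundity distributions
(zero-inflated negative binomial, or empirical count vectors). Lifetime
variances `σ²_m, σ²_f` enter Hill's overlapping-generations formula

    Ne_V = 4 N L / (2 + σ²_m + σ²_f)

with `N` spawners per season and `L` the mean generation length (parent age
at offspring birth, the spring after spawning). Forced semelparity (death
after the first mature season) isolates the effect of repeat spawning, and
sensitivity scans rescale fecundity variance (mean-preservingly) and
survival.

A synthetic-data module generates spawner tables, overdispersed family-size
tables and removal catches with this exact structure, so the whole chain is
testable without field data.

## Worked example

```python
import numpy as np
import ebreeders as eb
from ebreeders.breeders import MomentSummary

# seasonal Nb from census counts and family-size moments
nb_m = eb.per_sex_nb(MomentSummary(n=94, k_bar=4.2, v_k=118.2))
nb_f = eb.per_sex_nb(MomentSummary(n=132, k_bar=2.4, v_k=22.4))
print(f"Nb males   = {nb_m:.1f}")
print(f"Nb females = {nb_f:.1f}")
print(f"Nb combined = {eb.combine_nb(nb_m, nb_f):.1f}")
print(f"Nb (sex ratio only) = {eb.sex_ratio_nb(94, 132):.1f}")

# lifetime simulation under both parity modes
curve = eb.maturation_from_proportions(
    np.arange(3, 9), [0.10, 0.30, 0.60, 0.85, 0.95, 1.0])
survival = eb.SurvivalSchedule.flat(0.5)
fecundity = eb.SeasonalFecundityModel.seasonal_default()
cmp_ = eb.compare_parity(curve, survival, fecundity, n_boot=1000, seed=1)
print(cmp_.summary()[["mode", "mean_rs_m", "var_rs_m", "gen_length",
                      "ne_v_mean", "ne_v_sd"]].round(2).to_string(index=False))
```

prints

```
Nb males   = 13.5
Nb females = 30.7
Nb combined = 37.6
Nb (sex ratio only) = 219.6
       mode  mean_rs_m  var_rs_m  gen_length  ne_v_mean  ne_v_sd
iteroparous       2.15     62.87        5.93      82.54    46.47
semelparous       1.12     27.02        5.19     187.51   128.04
```

Reading: with 94 males and 132 females the sex ratio alone would support an
effective number near 220, but the huge family-size variance (V/k̄ ≈ 28 for
males) collapses the seasonal Nb to ~38 — an Nb/N ratio of about 0.17. In
the lifetime simulation, repeat spawners nearly double their mean lifetime
reproductive success relative to forced semelparity, but the extra variance
this creates roughly halves the per-generation Ne (and makes its estimate
far less noisy than under semelparity).

The same pipeline runs end to end from a YAML config:

```bash
ebreeders run --config examples/config.yaml --seed 42 --out out/
```

writing `spawners.tsv`, `families.tsv`, `removals.tsv`, `census.tsv`,
`table1.tsv` (seasonal Nb report), `table2.tsv` (stage-variance report),
`iteroparity.tsv`, `nev_replicates.tsv` and `manifest.json`. Individual
stages are available as `simulate-data`, `census`, `nb`, `family-variance`,
`simulate-ne`, `sensitivity` and `iteroparity` subcommands.

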