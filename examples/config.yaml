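# Demo configuration: a synthetic three-season spawner study with the
# calibrated seasonal family-size moments, plus the lifetime simulation.
seed: 42

synthetic:
  n_males: 98
  n_females: 108
  n_seasons: 3
  repeat_spawning_rate: 0.333
  age_range: [2, 8]
  family:
    males: {mean: 3.5, variance: 74.5}       # zero_mass defaults to 117/195
    females: {mean: 2.0, variance: 14.1}     # zero_mass defaults to 140/256
  family_correlation: 0.0
  juvenile_survival: 0.5
  removal: {capture_probability: 0.6, n_passes: 3}

bootstrap:
  n_boot: 1000

lifetime:
  mode: iteroparous
  n_boot: 1000
  n_males: 98
  n_females: 108
  census_size: null         # null -> n_males + n_females
  fecundity: default        # sex-specific zero-inflated negative binomial
  maturation: {3: 0.10, 4: 0.30, 5: 0.60, 6: 0.85, 7: 0.95, 8: 1.0}
  survival: {3: 0.5, 4: 0.5, 5: 0.5, 6: 0.5, 7: 0.5, 8: 0.5}

sensitivity:
  variance_multipliers: [0.5, 1.0, 2.0, 5.0, 10.0]
  survival_multipliers: [0.6, 1.0, 2.0]
  n_boot: 400
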