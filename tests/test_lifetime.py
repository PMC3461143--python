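"""Tests of the lifetime reproductive success simulator and Hill Ne."""

import numpy as np
import pandas as pd
import pytest

import ebreeders as eb
from ebreeders.lifetime import REPRODUCTIVE_AGES


def constant_fecundity(c):
    return eb.SeasonalFecundityModel({"M": eb.EmpiricalFecundity([c]),
                                      "F": eb.EmpiricalFecundity([c])})


class TestMaturationCurve:
    def test_direct_conditional_probabilities(self):
        curve = eb.maturation_from_proportions([3, 4, 5], [0.0, 0.5, 1.0])
        assert np.allclose(curve.m, [0.0, 0.5, 1.0])

    def test_constant_proportions_mean_no_new_maturation(self):
        curve = eb.maturation_from_proportions([3, 4, 5], [0.4, 0.4, 0.4])
        assert np.allclose(curve.m, [0.4, 0.0, 0.0])

    def test_non_monotone_proportions_are_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            curve = eb.maturation_from_proportions([3, 4, 5], [0.5, 0.3, 0.8])
        assert np.all(np.diff(curve.observed_proportions()) >= -1e-12)

    def test_saturated_then_dropping_proportions_rejected(self):
        with pytest.raises(eb.UndefinedInputError):
            eb.maturation_from_proportions([3, 4, 5], [1.0, 0.4, 0.4])

    def test_forward_simulation_round_trip(self):
        # simulate a cohort with known maturation probabilities and survival;
        # the proportions mature among survivors invert back to the curve
        m_true = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
        rng = np.random.default_rng(41)
        n = 200_000
        mature = np.zeros(n, dtype=bool)
        alive = np.ones(n, dtype=bool)
        o_observed = []
        for m_a in m_true:
            mature |= rng.random(n) < m_a
            o_observed.append(mature[alive].mean())
            alive &= rng.random(n) < 0.6  # survival independent of maturity
        curve = eb.maturation_from_proportions(REPRODUCTIVE_AGES, o_observed)
        assert np.allclose(curve.m, m_true, atol=0.02)


class TestAgeingErrorBootstrap:
    def _records(self, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.integers(3, 9, n)
        mature = rng.random(n) < (age - 2) / 6
        return pd.DataFrame({"age": age, "mature": mature})

    def test_no_error_gives_identical_replicates(self):
        records = self._records()
        res = eb.ageing_error_bootstrap(records, eb.AgeingErrorModel(0.0, 0.0),
                                        n_boot=20, seed=1)
        assert np.allclose(res.curves, res.point_m[None, :])
        assert res.mean_age_shift == 0.0

    def test_mean_age_shift_matches_error_mixture(self):
        # re-ageing quotas of 35% (+1 yr) and 18% (+2 yr) shift the mean
        # age of affected fish by 0.35 + 0.36 = 0.71 years
        res = eb.ageing_error_bootstrap(self._records(), eb.AgeingErrorModel(),
                                        n_boot=50, seed=2)
        assert res.mean_age_shift == pytest.approx(0.71, abs=0.01)

    def test_quota_capping_warns(self):
        # 3 eligible fish, quotas round(1.5) + round(1.5) = 4 > 3
        records = pd.DataFrame({"age": [5, 6, 7], "mature": [True, True, False]})
        with pytest.warns(RuntimeWarning):
            eb.ageing_error_bootstrap(records, eb.AgeingErrorModel(0.5, 0.5),
                                      n_boot=5, seed=3)


class TestHillNe:
    def test_reference_arithmetic(self):
        assert eb.hill_ne(100, 1, 1, 1) == pytest.approx(100.0)
        assert eb.hill_ne(50, 2, 0, 0) == pytest.approx(200.0)
        # plugging the seasonal census average, generation length and
        # lifetime variances of the study system into the formula
        assert eb.hill_ne(196, 6.2, 82.6, 22.7) == pytest.approx(45.3, abs=0.01)

    def test_exactly_linear_in_n_and_l(self):
        base = eb.hill_ne(123.0, 5.7, 31.4, 12.9)
        assert eb.hill_ne(246.0, 5.7, 31.4, 12.9) == 2 * base
        assert eb.hill_ne(123.0, 11.4, 31.4, 12.9) == 2 * base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(eb.UndefinedInputError):
            eb.hill_ne(0, 6.2, 1, 1)
        with pytest.raises(eb.UndefinedInputError):
            eb.hill_ne(100, 6.2, -1, 1)


class TestSimulateLifetimes:
    def test_deterministic_career(self):
        # certain maturation at 3, certain survival, constant fecundity:
        # iteroparous lifetime = 6c with zero variance, semelparous = c
        curve = eb.MaturationCurve(REPRODUCTIVE_AGES, [1, 1, 1, 1, 1, 1])
        surv = eb.SurvivalSchedule.flat(1.0)
        fec = constant_fecundity(4)
        it = eb.simulate_lifetimes(curve, surv, fec, n_males=20, n_females=20,
                                   n_boot=3, seed=1)
        assert (it.counts == 24).all()
        assert np.allclose(it.var_m, 0) and np.allclose(it.var_f, 0)
        se = eb.simulate_lifetimes(curve, surv, fec, n_males=20, n_females=20,
                                   mode="semelparous", n_boot=3, seed=1)
        assert (se.counts == 4).all()

    def test_modes_coincide_without_survival(self):
        curve = eb.maturation_from_proportions(REPRODUCTIVE_AGES,
                                               [0.4, 0.6, 0.8, 0.9, 1.0, 1.0])
        surv = eb.SurvivalSchedule.flat(0.0)
        fec = eb.SeasonalFecundityModel.seasonal_default()
        it = eb.simulate_lifetimes(curve, surv, fec, n_boot=5, seed=7)
        se = eb.simulate_lifetimes(curve, surv, fec, mode="semelparous",
                                   n_boot=5, seed=7)
        assert np.array_equal(it.counts, se.counts)

    def test_two_age_toy_matches_closed_form(self):
        # mature at 3 with certainty, survive one extra season w.p. s,
        # constant fecundity c: E[lifetime] = c (1 + s)
        s, c = 0.7, 5
        curve = eb.MaturationCurve(np.array([3, 4]), [1.0, 1.0])
        surv = eb.SurvivalSchedule(np.array([3, 4]), np.array([s, 0.0]))
        res = eb.simulate_lifetimes(curve, surv, constant_fecundity(c),
                                    n_males=25000, n_females=25000,
                                    n_boot=1, seed=13)
        expected = c * (1 + s)
        mc_se = c * np.sqrt(s * (1 - s) / 25000)
        assert res.mean_m[0] == pytest.approx(expected, abs=3 * mc_se)
        assert res.mean_f[0] == pytest.approx(expected, abs=3 * mc_se)

    def test_semelparous_lifetime_is_single_seasonal_draw(self, default_life_history):
        curve, surv, fec = default_life_history
        res = eb.simulate_lifetimes(curve, surv, fec, mode="semelparous",
                                    n_boot=20, seed=3)
        # every fish reproduces at most once: max count bounded by one draw,
        # and re-running iteroparously under the same seed dominates
        it = eb.simulate_lifetimes(curve, surv, fec, n_boot=20, seed=3)
        assert np.all(it.counts >= res.counts)

    def test_single_replicate_has_no_sd(self, default_life_history):
        curve, surv, fec = default_life_history
        res = eb.simulate_lifetimes(curve, surv, fec, n_boot=1, seed=5)
        assert res.ne_sd is None

    def test_missing_fecundity_cell_rejected(self, default_life_history):
        curve, surv, _ = default_life_history
        partial = eb.SeasonalFecundityModel({"M": eb.EmpiricalFecundity([1, 2])})
        with pytest.raises(eb.ConfigurationError):
            eb.simulate_lifetimes(curve, surv, partial, n_boot=2, seed=1)

    def test_deterministic_under_seed(self, default_life_history):
        curve, surv, fec = default_life_history
        a = eb.simulate_lifetimes(curve, surv, fec, n_boot=10, seed=99)
        b = eb.simulate_lifetimes(curve, surv, fec, n_boot=10, seed=99)
        assert np.array_equal(a.counts, b.counts)
        assert np.allclose(a.ne_v, b.ne_v, equal_nan=True)


class TestGenerationLength:
    def test_spring_after_spawning_convention(self):
        ped = pd.DataFrame({"parent_sex": ["M", "F"], "age": [5, 5],
                            "n_offspring": [3, 3]})
        gl = eb.generation_length(ped)
        assert gl.l_m == gl.l_f == gl.l_avg == 6.0

    def test_sex_average(self):
        ped = pd.DataFrame({"parent_sex": ["M", "F"], "age": [6, 5],
                            "n_offspring": [2, 2]})
        assert eb.generation_length(ped).l_avg == 6.5

    def test_offspring_weighting_and_sex_order(self):
        # male spawning ages stochastically dominate female ages -> l_m > l_f
        rng = np.random.default_rng(55)
        ped = pd.DataFrame({
            "parent_sex": ["M"] * 300 + ["F"] * 300,
            "age": np.concatenate([rng.integers(5, 9, 300),
                                   rng.integers(3, 7, 300)]),
            "n_offspring": rng.poisson(3, 600) + 1,
        })
        gl = eb.generation_length(ped)
        assert gl.l_m > gl.l_f


class TestParityComparison:
    def test_degenerate_config_exact_sixfold_gain(self):
        curve = eb.MaturationCurve(REPRODUCTIVE_AGES, [1, 1, 1, 1, 1, 1])
        surv = eb.SurvivalSchedule.flat(1.0)
        cmp_ = eb.compare_parity(curve, surv, constant_fecundity(3),
                                 n_males=10, n_females=10, n_boot=2, seed=1)
        assert cmp_.iteroparous.mean_m.mean() == 6 * cmp_.semelparous.mean_m.mean()

    def test_repeat_spawning_raises_variance_and_lowers_ne(self, default_life_history):
        curve, surv, fec = default_life_history
        cmp_ = eb.compare_parity(curve, surv, fec, n_boot=200, seed=11)
        it, se = cmp_.iteroparous, cmp_.semelparous
        assert se.mean_m.mean() < it.mean_m.mean()
        assert se.mean_f.mean() < it.mean_f.mean()
        assert se.ne_mean > it.ne_mean
        assert se.ne_sd > it.ne_sd
        summary = cmp_.summary()
        assert list(summary["mode"]) == ["iteroparous", "semelparous"]


class TestVarianceScaling:
    def test_mean_preserved_exactly_and_empirically(self):
        dist = eb.ZINBFecundity(3.5, 74.5, 0.6)
        for mult in (0.5, 2.0, 10.0):
            scaled = dist.with_variance_scaled(mult)
            assert scaled.mean == dist.mean
            assert scaled.variance == pytest.approx(74.5 * mult)
        rng = np.random.default_rng(61)
        x = dist.with_variance_scaled(10.0).sample(rng, 4_000_000)
        se = np.sqrt(745 / 4e6)
        assert x.mean() == pytest.approx(3.5, abs=4 * se)

    def test_empirical_distribution_refuses_scaling(self):
        dist = eb.EmpiricalFecundity([0, 1, 5])
        with pytest.raises(eb.InadmissibleMomentsError):
            dist.with_variance_scaled(2.0)
        assert dist.with_variance_scaled(1.0) is dist


class TestSensitivityScan:
    def test_unit_multipliers_reproduce_baseline(self, default_life_history):
        curve, surv, fec = default_life_history
        grid = eb.sensitivity_scan(curve, surv, fec, variance_multipliers=(1.0,),
                                   survival_multipliers=(1.0,), n_boot=50, seed=71)
        base = eb.simulate_lifetimes(curve, surv, fec, n_boot=50, seed=71)
        assert grid["ne_v_mean"].iloc[0] == pytest.approx(base.ne_mean)
        assert grid["ne_v_plugin"].iloc[0] == pytest.approx(base.ne_plugin)

    def test_inadmissible_variance_point_flagged(self, default_life_history):
        curve, surv, fec = default_life_history
        # far below the zero-inflated Poisson floor
        grid = eb.sensitivity_scan(curve, surv, fec, variance_multipliers=(0.01, 1.0),
                                   survival_multipliers=(1.0,), n_boot=20, seed=3)
        assert not grid[grid["variance_multiplier"] == 0.01]["admissible"].iloc[0]
        assert np.isnan(grid[grid["variance_multiplier"] == 0.01]["ne_v_mean"].iloc[0])
        assert grid[grid["variance_multiplier"] == 1.0]["admissible"].iloc[0]
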