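"""Tests of the synthetic spawner/family/removal data generators."""

import numpy as np
import pandas as pd
import pytest

import ebreeders as eb
from ebreeders.synthetic import zinb_parameters, zinb_sample


class TestGenerateSpawners:
    def test_degenerate_sex_composition(self):
        spec = eb.SpawnerPopulationSpec(n_males=0, n_females=5, n_seasons=1, seed=1)
        table = eb.generate_spawners(spec)
        assert len(table) == 5
        assert (table["sex"] == "F").all()

    def test_no_repeats_when_rate_zero(self):
        spec = eb.SpawnerPopulationSpec(n_males=30, n_females=30, n_seasons=4,
                                        repeat_spawning_rate=0.0, seed=2)
        table = eb.generate_spawners(spec)
        assert table.groupby("id")["season"].nunique().max() == 1

    def test_season_composition_and_age_increment(self):
        spec = eb.SpawnerPopulationSpec(n_males=40, n_females=50, n_seasons=3,
                                        repeat_spawning_rate=0.5, seed=3)
        table = eb.generate_spawners(spec)
        sizes = table.groupby(["season", "sex"]).size().unstack()
        assert (sizes["M"] == 40).all() and (sizes["F"] == 50).all()
        repeats = table[table.duplicated("id", keep=False)]
        for _, grp in repeats.groupby("id"):
            grp = grp.sort_values("season")
            assert np.all(np.diff(grp["season"]) == 1)
            assert np.all(np.diff(grp["true_age"]) == 1)

    def test_repeat_fraction_matches_rate(self):
        # geometric persistence: P(seen in >1 season) = repeat rate for any
        # cohort that has at least one later season to persist into
        rate = 1 / 3
        spec = eb.SpawnerPopulationSpec(n_males=20000, n_females=20000,
                                        n_seasons=5, repeat_spawning_rate=rate,
                                        seed=4)
        table = eb.generate_spawners(spec)
        first = table.groupby("id")["season"].min()
        n_seasons = table.groupby("id")["season"].nunique()
        cohort1 = n_seasons[first == 1]
        frac = (cohort1 > 1).mean()
        se = np.sqrt(rate * (1 - rate) / len(cohort1))
        assert abs(frac - rate) < 4 * se

    def test_deterministic_under_fixed_seed(self):
        spec = eb.SpawnerPopulationSpec(n_males=25, n_females=25, n_seasons=3, seed=7)
        pd.testing.assert_frame_equal(eb.generate_spawners(spec),
                                      eb.generate_spawners(spec))

    def test_invalid_probability_vector_rejected(self):
        spec = eb.SpawnerPopulationSpec(n_males=5, n_females=5,
                                        age_distribution=np.array([0.5, 0.2]))
        with pytest.raises(eb.ConfigurationError):
            eb.generate_spawners(spec)


class TestFamilySizes:
    def test_zinb_moment_matching(self):
        # heavily overdispersed target with >50% zero mass
        rng = np.random.default_rng(11)
        x = zinb_sample(rng, 10 ** 6, 4.2, 118.2, 0.6)
        assert x.mean() == pytest.approx(4.2, rel=0.01)
        assert x.var(ddof=1) == pytest.approx(118.2, rel=0.03)

    def test_poisson_index_of_variability_near_one(self):
        parents = eb.generate_spawners(
            eb.SpawnerPopulationSpec(n_males=20000, n_females=0, n_seasons=1, seed=5))
        fams = eb.sample_family_sizes(
            parents, eb.FamilySizeSpec(2.0, 2.0, distribution_family="poisson"),
            seed=6)
        counts = fams[fams["offspring_age_class"] == 1]["n_offspring"]
        assert counts.var(ddof=1) / counts.mean() == pytest.approx(1.0, abs=0.05)

    def test_zero_mean_gives_all_zeros(self):
        parents = eb.generate_spawners(
            eb.SpawnerPopulationSpec(n_males=50, n_females=50, n_seasons=1, seed=8))
        fams = eb.sample_family_sizes(parents, eb.FamilySizeSpec(0.0, 0.0), seed=9)
        assert (fams["n_offspring"] == 0).all()

    def test_inadmissible_moments_rejected(self):
        parents = eb.generate_spawners(
            eb.SpawnerPopulationSpec(n_males=5, n_females=5, n_seasons=1, seed=1))
        with pytest.raises(eb.InadmissibleMomentsError):
            eb.sample_family_sizes(
                parents,
                eb.FamilySizeSpec(5.0, 2.0, distribution_family="nb"), seed=1)
        with pytest.raises(eb.InadmissibleMomentsError):
            zinb_parameters(4.0, 1.0, 0.6)

    def test_family_correlation_inflates_stage3_dispersion(self):
        # correlated survival concentrates juvenile mortality within families,
        # inflating the age-3 variance-to-mean ratio relative to random thinning
        parents = eb.generate_spawners(
            eb.SpawnerPopulationSpec(n_males=40000, n_females=0, n_seasons=1, seed=12))
        r3 = {}
        for rho in (0.0, 0.6):
            fams = eb.sample_family_sizes(
                parents, eb.FamilySizeSpec(4.2, 40.0, family_correlation=rho,
                                           zero_mass=0.3), seed=13)
            c3 = fams[fams["offspring_age_class"] == 3]["n_offspring"]
            r3[rho] = c3.var(ddof=1) / c3.mean()
        assert r3[0.6] > r3[0.0] * 1.05

    def test_table_schema_and_determinism(self):
        parents = eb.generate_spawners(
            eb.SpawnerPopulationSpec(n_males=30, n_females=30, n_seasons=2, seed=14))
        spec = {"M": eb.FamilySizeSpec(4.2, 118.2), "F": eb.FamilySizeSpec(2.4, 22.4)}
        a = eb.sample_family_sizes(parents, spec, seed=15)
        b = eb.sample_family_sizes(parents, spec, seed=15)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) == {"parent_id", "season", "parent_sex",
                                  "offspring_age_class", "n_offspring"}
        assert set(a["offspring_age_class"]) == {1, 3}
        # age-3 counts never exceed age-1 counts for the same parent-season
        wide = a.pivot_table(index=["parent_id", "season"],
                             columns="offspring_age_class", values="n_offspring")
        assert (wide[3] <= wide[1]).all()


class TestCorruptAges:
    def test_no_error_model_leaves_ages_unchanged(self):
        records = pd.DataFrame({"true_age": [2, 3, 5, 8]})
        out = eb.corrupt_ages(records, eb.AgeingErrorModel(0.0, 0.0), seed=1)
        assert (out["observed_age"] == out["true_age"]).all()

    def test_certain_one_year_underestimate(self):
        records = pd.DataFrame({"true_age": [2, 3, 5, 8]})
        out = eb.corrupt_ages(records, eb.AgeingErrorModel(1.0, 0.0), seed=1)
        assert list(out["observed_age"]) == [2, 2, 4, 7]

    def test_mean_shift_matches_error_mixture(self):
        # expected underestimate = 0.35*1 + 0.18*2 = 0.71 among affected fish
        records = pd.DataFrame({"true_age": np.full(10 ** 5, 5)})
        out = eb.corrupt_ages(records, eb.AgeingErrorModel(), seed=21)
        shift = (out["true_age"] - out["observed_age"]).mean()
        se = np.sqrt((0.35 + 4 * 0.18 - 0.71 ** 2) / 10 ** 5)
        assert abs(shift - 0.71) < 4 * se


class TestRemovalSampling:
    def test_certain_capture_depletes_on_first_pass(self):
        catches = eb.sample_removal_counts(eb.RemovalSpec(42, 1.0), seed=1)
        assert list(catches) == [42, 0, 0]

    def test_zero_capture_probability(self):
        catches = eb.sample_removal_counts(eb.RemovalSpec(42, 0.0), seed=1)
        assert list(catches) == [0, 0, 0]

    def test_geometric_depletion_expectation(self):
        # E[catches] = (Np, Npq, Npq^2) = (50, 25, 12.5) for N=100, p=0.5
        reps = np.array([eb.sample_removal_counts(eb.RemovalSpec(100, 0.5), seed=s)
                         for s in range(20000)])
        means = reps.mean(axis=0)
        assert np.allclose(means, [50, 25, 12.5], atol=0.2)
        assert (reps.sum(axis=1) <= 100).all()
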