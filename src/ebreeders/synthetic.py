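"""Synthetic spawner, family-size and removal-count tables.

Generates tabular data with the statistical structure that the downstream
estimators assume for a small stream-resident brown trout population:

* spawner tables with configurable sex ratio, age structure and repeat
  spawning across consecutive seasons (iteroparity);
* heavily overdispersed family-size (assigned-offspring) distributions,
  modelled as zero-inflated negative binomials matched to a target mean and
  variance, with optional family-correlated juvenile survival thinning the
  age-1 counts down to age-3 counts;
* scale-reading ageing errors (systematic underestimation for older fish);
* multi-pass removal (depletion) catch vectors for the census estimator.

All sampling is driven by :class:`numpy.random.Generator`; a fixed seed gives
bit-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InadmissibleMomentsError

__all__ = [
    "SpawnerPopulationSpec",
    "FamilySizeSpec",
    "AgeingErrorModel",
    "RemovalSpec",
    "DEFAULT_ZERO_MASS",
    "generate_spawners",
    "sample_family_sizes",
    "corrupt_ages",
    "sample_removal_counts",
    "zinb_parameters",
    "zinb_sample",
]

# Fraction of sampled mature fish that were assigned no offspring at all, by
# parent sex; used as the default zero-inflation mass of family-size draws.
DEFAULT_ZERO_MASS = {"M": 117 / 195, "F": 140 / 256}

# Default age distribution of spawners over ages 2..8 (mean ~5.5 years,
# females/males both maturing mostly at ages 4-7).
_DEFAULT_AGE_PROBS = np.array([0.02, 0.08, 0.15, 0.25, 0.25, 0.15, 0.10])


@dataclass
class SpawnerPopulationSpec:
    """Configuration of a synthetic spawning population.

    ``repeat_spawning_rate`` is the probability that a spawner mature in
    season *t* is mature again in season *t+1* (geometric persistence), so
    the expected fraction of spawners observed in more than one season
    equals the rate itself.
    """

    n_males: int
    n_females: int
    age_range: tuple[int, int] = (2, 8)
    age_distribution: np.ndarray | None = None
    repeat_spawning_rate: float = 1 / 3
    n_seasons: int = 3
    length_median_intercept: float = 75.0  # mm
    length_median_slope: float = 22.0  # mm per year of age
    length_log_sd: float = 0.08
    seed: int | None = None

    def resolved_age_distribution(self) -> np.ndarray:
        lo, hi = self.age_range
        n_ages = hi - lo + 1
        if self.age_distribution is None:
            if (lo, hi) == (2, 8):
                return _DEFAULT_AGE_PROBS.copy()
            return np.full(n_ages, 1.0 / n_ages)
        p = np.asarray(self.age_distribution, dtype=float)
        if p.shape != (n_ages,):
            raise ConfigurationError(
                f"age_distribution must have {n_ages} entries for ages {lo}..{hi}"
            )
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ConfigurationError("age_distribution must be a probability vector")
        return p

    def validate(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ConfigurationError("spawner counts must be non-negative")
        if not 0 <= self.repeat_spawning_rate <= 1:
            raise ConfigurationError("repeat_spawning_rate must lie in [0, 1]")
        if self.n_seasons < 1:
            raise ConfigurationError("n_seasons must be at least 1")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ConfigurationError("invalid age_range")
        self.resolved_age_distribution()


@dataclass
class FamilySizeSpec:
    """Target moments and shape of the per-parent offspring-count distribution.

    ``family_correlation`` (rho in [0, 1]) controls family-specific juvenile
    survival between the age-1 and age-3 offspring classes: each family's
    survival probability is beta-distributed with mean ``juvenile_survival``
    and variance ``rho * s * (1 - s)``. rho = 0 collapses to independent
    binomial thinning (random survival).
    """

    target_mean: float
    target_variance: float
    family_correlation: float = 0.0
    distribution_family: str = "zinb"  # zinb | nb | poisson
    zero_mass: float | None = None
    juvenile_survival: float = 0.5

    def validate(self) -> None:
        if self.target_mean < 0 or self.target_variance < 0:
            raise ConfigurationError("family-size moments must be non-negative")
        if not 0 <= self.family_correlation <= 1:
            raise ConfigurationError("family_correlation must lie in [0, 1]")
        if not 0 < self.juvenile_survival <= 1:
            raise ConfigurationError("juvenile_survival must lie in (0, 1]")
        if self.distribution_family not in {"zinb", "nb", "poisson"}:
            raise ConfigurationError(
                f"unknown distribution_family {self.distribution_family!r}"
            )


@dataclass
class AgeingErrorModel:
    """Scale-reading ageing error: systematic underestimation for older fish.

    Defaults reflect the observed error structure: among fish aged 3 years or
    older, age is underestimated by 1 year with probability 0.35 and by
    2 years with probability 0.18; younger fish are aged from length and are
    unaffected.
    """

    p_under1: float = 0.35
    p_under2: float = 0.18
    min_age_affected: int = 3

    def validate(self) -> None:
        if min(self.p_under1, self.p_under2) < 0 or self.p_under1 + self.p_under2 > 1:
            raise ConfigurationError("require p_under1, p_under2 >= 0 and sum <= 1")


@dataclass
class RemovalSpec:
    """Forward model for multi-pass removal (depletion) sampling."""

    true_abundance: int
    capture_probability: float
    n_passes: int = 3

    def validate(self) -> None:
        if self.true_abundance < 0:
            raise ConfigurationError("true_abundance must be non-negative")
        if not 0 <= self.capture_probability <= 1:
            raise ConfigurationError("capture_probability must lie in [0, 1]")
        if self.n_passes < 2:
            raise ConfigurationError("need at least 2 passes for identifiability")


# ---------------------------------------------------------------------------
# Spawner tables
# ---------------------------------------------------------------------------

def generate_spawners(spec: SpawnerPopulationSpec) -> pd.DataFrame:
    """Generate a spawner table across seasons.

    Season 1 holds exactly ``n_males + n_females`` distinct individuals.
    Each spawner persists into the next season with probability
    ``repeat_spawning_rate`` (age incremented); new recruits top each later
    season back up to the configured per-sex counts.

    Returns a DataFrame with columns
    ``id, season, sex, true_age, length_mm`` (one row per fish per season).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages_support = np.arange(lo, hi + 1)
    age_probs = spec.resolved_age_distribution()

    next_id = 1
    rows: list[pd.DataFrame] = []
    cur_id = np.empty(0, dtype=int)
    cur_sex = np.empty(0, dtype="U1")
    cur_age = np.empty(0, dtype=int)

    for season in range(1, spec.n_seasons + 1):
        if season > 1:
            keep = rng.random(cur_id.size) < spec.repeat_spawning_rate
            cur_id, cur_sex, cur_age = cur_id[keep], cur_sex[keep], cur_age[keep] + 1
        new_parts = []
        for sex, target in (("M", spec.n_males), ("F", spec.n_females)):
            have = int(np.sum(cur_sex == sex))
            need = max(target - have, 0)
            if need:
                ids = np.arange(next_id, next_id + need)
                next_id += need
                new_parts.append(
                    (ids, np.full(need, sex), rng.choice(ages_support, need, p=age_probs))
                )
        if new_parts:
            cur_id = np.concatenate([cur_id] + [p[0] for p in new_parts])
            cur_sex = np.concatenate([cur_sex] + [p[1] for p in new_parts])
            cur_age = np.concatenate([cur_age] + [p[2] for p in new_parts])
        median = spec.length_median_intercept + spec.length_median_slope * cur_age
        length = median * np.exp(rng.normal(0.0, spec.length_log_sd, cur_id.size))
        rows.append(
            pd.DataFrame(
                {
                    "id": cur_id,
                    "season": season,
                    "sex": cur_sex,
                    "true_age": cur_age,
                    "length_mm": np.round(length, 1),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Family sizes (zero-inflated negative binomial machinery)
# ---------------------------------------------------------------------------

def zinb_parameters(mean: float, variance: float, zero_mass: float) -> tuple[float, float, float]:
    """Solve the zero-inflated negative binomial for target total moments.

    The mixture puts mass ``pi = zero_mass`` on zero and ``1 - pi`` on a
    negative binomial with mean ``m`` and variance ``v`` chosen so that the
    mixture's overall mean and variance equal the targets:

        mean = (1 - pi) m
        variance = (1 - pi) v + pi (1 - pi) m**2

    Returns ``(pi, m, r)`` with ``r`` the NB dispersion (``v = m + m**2/r``);
    ``r = inf`` denotes a Poisson component (``v ~= m``).

    Raises :class:`InadmissibleMomentsError` if the implied component
    variance falls below its Poisson floor.
    """
    if not 0 <= zero_mass < 1:
        raise InadmissibleMomentsError("zero_mass must lie in [0, 1)")
    if mean <= 0:
        raise InadmissibleMomentsError("mean must be positive for a ZINB")
    pi = zero_mass
    m = mean / (1.0 - pi)
    v = variance / (1.0 - pi) - pi * m * m
    if v < m * (1.0 - 1e-9):
        raise InadmissibleMomentsError(
            f"targets (mean={mean}, variance={variance}, zero_mass={zero_mass}) "
            f"imply component variance {v:.3f} below the Poisson floor {m:.3f}"
        )
    if v <= m * (1.0 + 1e-9):
        return pi, m, np.inf
    r = m * m / (v - m)
    return pi, m, r


def zinb_sample(rng: np.random.Generator, size, mean: float, variance: float,
                zero_mass: float = 0.0) -> np.ndarray:
    """Draw zero-inflated negative binomial counts with the given total moments."""
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    pi, m, r = zinb_parameters(mean, variance, zero_mass)
    if np.isinf(r):
        x = rng.poisson(m, size)
    else:
        lam = rng.gamma(shape=r, scale=m / r, size=size)
        x = rng.poisson(lam)
    if pi > 0:
        x = np.where(rng.random(size) < pi, 0, x)
    return x.astype(np.int64)


def _draw_counts(rng: np.random.Generator, n: int, spec: FamilySizeSpec,
                 sex: str | None) -> np.ndarray:
    if spec.target_mean == 0:
        return np.zeros(n, dtype=np.int64)
    fam = spec.distribution_family
    if fam == "poisson":
        return rng.poisson(spec.target_mean, n).astype(np.int64)
    if fam == "nb":
        zero_mass = 0.0
    else:
        zero_mass = spec.zero_mass
        if zero_mass is None:
            zero_mass = DEFAULT_ZERO_MASS.get(sex or "", 0.0)
    return zinb_sample(rng, n, spec.target_mean, spec.target_variance, zero_mass)


def _family_survival(rng: np.random.Generator, n: int, s: float, rho: float) -> np.ndarray:
    """Per-family survival probabilities with mean s and variance rho*s*(1-s)."""
    if rho == 0 or s == 1.0:
        return np.full(n, s)
    if rho == 1:
        return (rng.random(n) < s).astype(float)
    nu = (1.0 - rho) / rho  # total beta concentration minus ... alpha+beta = nu
    return rng.beta(s * nu, (1.0 - s) * nu, n)


def sample_family_sizes(parents: pd.DataFrame,
                        spec: FamilySizeSpec | dict,
                        seed: int | None = None) -> pd.DataFrame:
    """Sample assigned-offspring counts for every parent in a spawner table.

    ``spec`` is either one :class:`FamilySizeSpec` applied to both sexes or a
    mapping ``{"M": spec, "F": spec}``. Per parent-season, an age-1 count is
    drawn from the configured distribution and thinned to an age-3 count by
    (possibly family-correlated) juvenile survival.

    Returns the long-format family table with columns
    ``parent_id, season, parent_sex, offspring_age_class, n_offspring``.
    """
    specs: dict[str, FamilySizeSpec]
    if isinstance(spec, FamilySizeSpec):
        specs = {"M": spec, "F": spec}
    else:
        specs = dict(spec)
    for s in specs.values():
        s.validate()
    rng = np.random.default_rng(seed)

    out = []
    for sex in ("M", "F"):
        sub = parents[parents["sex"] == sex]
        if sub.empty:
            continue
        sx = specs[sex]
        n = len(sub)
        n1 = _draw_counts(rng, n, sx, sex)
        p_fam = _family_survival(rng, n, sx.juvenile_survival, sx.family_correlation)
        n3 = rng.binomial(n1, p_fam)
        for age_class, counts in ((1, n1), (3, n3)):
            out.append(
                pd.DataFrame(
                    {
                        "parent_id": sub["id"].to_numpy(),
                        "season": sub["season"].to_numpy(),
                        "parent_sex": sex,
                        "offspring_age_class": age_class,
                        "n_offspring": counts,
                    }
                )
            )
    if not out:
        return pd.DataFrame(
            columns=["parent_id", "season", "parent_sex", "offspring_age_class", "n_offspring"]
        )
    return (
        pd.concat(out, ignore_index=True)
        .sort_values(["season", "parent_sex", "offspring_age_class", "parent_id"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Ageing errors and removal sampling
# ---------------------------------------------------------------------------

def corrupt_ages(records: pd.DataFrame, model: AgeingErrorModel,
                 seed: int | None = None) -> pd.DataFrame:
    """Add an ``observed_age`` column with scale-reading underestimation.

    Fish with ``true_age >= min_age_affected`` have their age underestimated
    by 1 year with probability ``p_under1`` and by 2 years with probability
    ``p_under2``, independently per fish; younger fish are unaffected.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    out = records.copy()
    age = out["true_age"].to_numpy()
    u = rng.random(len(out))
    shift = np.where(u < model.p_under1, 1, np.where(u < model.p_under1 + model.p_under2, 2, 0))
    shift = np.where(age >= model.min_age_affected, shift, 0)
    out["observed_age"] = age - shift
    return out


def sample_removal_counts(spec: RemovalSpec, seed: int | None = None) -> np.ndarray:
    """Simulate successive removal-pass catches (fish removed after capture)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    remaining = spec.true_abundance
    catches = np.zeros(spec.n_passes, dtype=np.int64)
    for i in range(spec.n_passes):
        c = rng.binomial(remaining, spec.capture_probability) if remaining else 0
        catches[i] = c
        remaining -= c
    return catches
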