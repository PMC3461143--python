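"""YAML-backed run configuration.

A single configuration dict drives every pipeline stage; per-stage seeds are
derived from the master ``seed`` by fixed offsets so stages are individually
reproducible. ``load_config`` merges a user file over structural defaults —
deliberately *not* including a fecundity model, which the lifetime stage
requires to be stated explicitly (``"default"`` selects the calibrated
seasonal zero-inflated negative binomial model).
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .lifetime import (EmpiricalFecundity, MaturationCurve, SeasonalFecundityModel,
                       SurvivalSchedule, ZINBFecundity, maturation_from_proportions)
from .synthetic import FamilySizeSpec, SpawnerPopulationSpec

__all__ = ["DEFAULT_CONFIG", "load_config", "default_config", "stage_seed",
           "build_spawner_spec", "build_family_specs", "build_curve",
           "build_survival", "build_fecundity"]

# Seed offsets per stage (master seed + offset), fixed for replicable
# stage isolation.
_STAGE_OFFSETS = {"data": 1, "census": 2, "nb": 3, "lifetime": 4, "sensitivity": 5}

# Observed proportions mature at age; package default chosen to give a mean
# spawner age near 6 years (see docs/methods.md).
_DEFAULT_MATURATION_O = {3: 0.10, 4: 0.30, 5: 0.60, 6: 0.85, 7: 0.95, 8: 1.0}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "n_males": 98,
        "n_females": 108,
        "n_seasons": 3,
        "repeat_spawning_rate": 1 / 3,
        "age_range": [2, 8],
        "family": {
            "males": {"mean": 3.5, "variance": 74.5},
            "females": {"mean": 2.0, "variance": 14.1},
        },
        "family_correlation": 0.0,
        "juvenile_survival": 0.5,
        "removal": {"capture_probability": 0.6, "n_passes": 3},
    },
    "bootstrap": {"n_boot": 1000},
    "lifetime": {
        "mode": "iteroparous",
        "n_boot": 1000,
        "n_males": 98,
        "n_females": 108,
        "census_size": None,  # None -> n_males + n_females
        "maturation": dict(_DEFAULT_MATURATION_O),
        "survival": {a: 0.5 for a in range(3, 9)},
        # "fecundity" must be given explicitly (e.g. "default")
    },
    "sensitivity": {
        "variance_multipliers": [0.5, 1.0, 2.0, 5.0, 10.0],
        "survival_multipliers": [0.6, 1.0, 2.0],
        "n_boot": 200,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_config() -> dict:
    """Full demo configuration (including the default fecundity model)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["lifetime"]["fecundity"] = "default"
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML configuration merged over the structural defaults."""
    if path is None:
        return default_config()
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigurationError("top-level config must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def stage_seed(config: dict, stage: str) -> int:
    """Per-stage seed = master seed + fixed stage offset (mod 2**31)."""
    if stage not in _STAGE_OFFSETS:
        raise ConfigurationError(f"unknown stage {stage!r}")
    return (int(config.get("seed", 0)) + _STAGE_OFFSETS[stage]) % (2 ** 31)


# ---------------------------------------------------------------------------
# Builders: config fragments -> domain objects
# ---------------------------------------------------------------------------

def build_spawner_spec(config: dict) -> SpawnerPopulationSpec:
    syn = config["synthetic"]
    return SpawnerPopulationSpec(
        n_males=int(syn["n_males"]), n_females=int(syn["n_females"]),
        age_range=tuple(syn.get("age_range", (2, 8))),
        repeat_spawning_rate=float(syn.get("repeat_spawning_rate", 1 / 3)),
        n_seasons=int(syn.get("n_seasons", 3)),
        seed=stage_seed(config, "data"),
    )


def build_family_specs(config: dict) -> dict[str, FamilySizeSpec]:
    syn = config["synthetic"]
    fam = syn.get("family")
    if not fam:
        raise ConfigurationError("missing key synthetic.family")
    out = {}
    for sex, key in (("M", "males"), ("F", "females")):
        sub = fam.get(key)
        if sub is None:
            raise ConfigurationError(f"missing key synthetic.family.{key}")
        out[sex] = FamilySizeSpec(
            target_mean=float(sub["mean"]), target_variance=float(sub["variance"]),
            family_correlation=float(syn.get("family_correlation", 0.0)),
            distribution_family=sub.get("distribution", "zinb"),
            zero_mass=sub.get("zero_mass"),
            juvenile_survival=float(syn.get("juvenile_survival", 0.5)),
        )
    return out


def build_curve(config: dict) -> MaturationCurve:
    o_map = config["lifetime"].get("maturation")
    if not o_map:
        raise ConfigurationError("missing key lifetime.maturation")
    ages = np.array(sorted(int(a) for a in o_map), dtype=int)
    o = np.array([float(o_map[a] if a in o_map else o_map[str(a)]) for a in ages])
    return maturation_from_proportions(ages, o)


def build_survival(config: dict) -> SurvivalSchedule:
    s_map = config["lifetime"].get("survival")
    if not s_map:
        raise ConfigurationError("missing key lifetime.survival")
    ages = np.array(sorted(int(a) for a in s_map), dtype=int)
    s = np.array([float(s_map[a] if a in s_map else s_map[str(a)]) for a in ages])
    return SurvivalSchedule(ages=ages, s=s)


def build_fecundity(config: dict) -> SeasonalFecundityModel:
    spec = config["lifetime"].get("fecundity")
    if spec is None:
        raise ConfigurationError(
            "missing key lifetime.fecundity (set to 'default' for the "
            "calibrated seasonal model, or give per-sex moments/counts)")
    if spec == "default":
        return SeasonalFecundityModel.seasonal_default()
    entries: dict = {}
    for sex, key in (("M", "males"), ("F", "females")):
        sub = spec.get(key)
        if sub is None:
            raise ConfigurationError(f"missing key lifetime.fecundity.{key}")
        if "counts" in sub:
            entries[sex] = EmpiricalFecundity(sub["counts"])
        else:
            entries[sex] = ZINBFecundity(
                float(sub["mean"]), float(sub["variance"]),
                float(sub.get("zero_mass", 0.0)))
    return SeasonalFecundityModel(entries)
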