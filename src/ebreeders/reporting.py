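"""Report tables, descriptive summaries and the end-to-end pipeline.

Builds the two central report tables — the seasonal effective-breeder table
(census counts, family-size moments, per-sex and combined Nb with bootstrap
CIs) and the stage-wise family-variance table (index of variability, its
value scaled to replacement mean family size, and the resulting Nb/N) —
plus descriptive iteroparity summaries and a machine-readable run manifest.

``run_pipeline`` orchestrates: synthetic data -> removal census -> seasonal
Nb -> family variance -> lifetime simulation, writing TSV reports and
``manifest.json``; any stage failure renames completed outputs with a
``.partial`` suffix and re-raises.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breeders import MomentSummary, nb_bootstrap_ci, per_sex_nb, sex_ratio_nb
from .census import estimate_census
from .config import (build_curve, build_family_specs, build_fecundity,
                     build_spawner_spec, build_survival, stage_seed)
from .errors import ConfigurationError
from .family_variance import StageIndex, stage_change
from .lifetime import simulate_lifetimes
from .synthetic import RemovalSpec, generate_spawners, sample_family_sizes, \
    sample_removal_counts, corrupt_ages, AgeingErrorModel

__all__ = ["describe_iteroparity", "build_table1", "build_table2",
           "run_pipeline", "plot_ne_histogram", "plot_sensitivity"]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def describe_iteroparity(spawners: pd.DataFrame) -> pd.DataFrame:
    """Per-sex proportions of spawners by number of seasons observed mature.

    Returns a tidy frame with columns ``sex, n_seasons, proportion``;
    proportions sum to 1 within each sex.
    """
    per_id = spawners.groupby(["sex", "id"])["season"].nunique().rename("n_seasons")
    out = []
    for sex, sub in per_id.groupby(level="sex"):
        counts = sub.value_counts().sort_index()
        props = counts / counts.sum()
        for n_seasons, p in props.items():
            out.append({"sex": sex, "n_seasons": int(n_seasons), "proportion": float(p)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _counts_by(families: pd.DataFrame, season, sex: str, age_class: int) -> np.ndarray:
    sel = families[
        (families["season"] == season)
        & (families["parent_sex"] == sex)
        & (families["offspring_age_class"] == age_class)
    ]
    return sel["n_offspring"].to_numpy(dtype=float)


def _census_lookup(census: pd.DataFrame, season, sex: str) -> float:
    sel = census[(census["season"] == season) & (census["sex"] == sex)]
    if sel.empty:
        raise ConfigurationError(f"no census estimate for season={season}, sex={sex}")
    return float(sel["n_hat"].iloc[0])


def build_table1(families: pd.DataFrame, census: pd.DataFrame,
                 n_boot: int = 1000, seed: int | None = None,
                 age_class: int = 1) -> pd.DataFrame:
    """Seasonal effective-breeder table (one row per season plus an
    arithmetic-mean ``average`` row)."""
    seasons = sorted(families["season"].unique())
    rows = []
    for i, season in enumerate(seasons):
        cm = _counts_by(families, season, "M", age_class)
        cf = _counts_by(families, season, "F", age_class)
        n_m = _census_lookup(census, season, "M")
        n_f = _census_lookup(census, season, "F")
        boot_seed = None if seed is None else (seed + i) % (2 ** 31)
        res = nb_bootstrap_ci(cm, cf, n_m=n_m, n_f=n_f, n_boot=n_boot, seed=boot_seed)
        mm = MomentSummary.from_counts(cm, n=n_m)
        mf = MomentSummary.from_counts(cf, n=n_f)
        rows.append({
            "season": season, "n_m": n_m, "n_f": n_f, "n_total": n_m + n_f,
            "nb_sex_ratio": res.nb_sex_ratio,
            "nb_sex_ratio_over_n": res.nb_sex_ratio / (n_m + n_f),
            "k_m": mm.k_bar, "v_m": mm.v_k, "nb_m": res.nb_m,
            "k_f": mf.k_bar, "v_f": mf.v_k, "nb_f": res.nb_f,
            "nb_combined": res.nb_combined,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "nb_over_n": res.nb_over_n,
        })
    table = pd.DataFrame(rows)
    avg = table.drop(columns=["season"]).mean(numeric_only=True)
    avg["season"] = "average"
    return pd.concat([table, avg.to_frame().T[table.columns]], ignore_index=True)


def build_table2(families: pd.DataFrame, census: pd.DataFrame,
                 seasons=None) -> pd.DataFrame:
    """Stage-wise family-variance table: per sex and season, the age-1 and
    age-3 indices of variability, their values scaled to mean family size 2,
    the implied Nb/N ratios and the percent change between stages."""
    if seasons is None:
        seasons = sorted(families["season"].unique())
    rows = []
    for sex in ("M", "F"):
        for season in seasons:
            n_hat = _census_lookup(census, season, sex)
            stages = {}
            for age_class in (1, 3):
                c = _counts_by(families, season, sex, age_class)
                if c.size == 0 or c.mean() == 0:
                    stages[age_class] = None
                    continue
                stages[age_class] = StageIndex.from_moments(
                    age_class, float(c.mean()), float(c.var(ddof=1)))
            s1, s3 = stages[1], stages[3]
            row = {"sex": sex, "season": season, "n": n_hat}
            for label, st in (("1", s1), ("3", s3)):
                if st is None:
                    row.update({f"k{label}": np.nan, f"v{label}": np.nan,
                                f"r{label}": np.nan, f"r_star{label}": np.nan,
                                f"nb_over_n_{label}": np.nan})
                else:
                    row.update({f"k{label}": st.k, f"v{label}": st.v,
                                f"r{label}": st.r, f"r_star{label}": st.r_star,
                                f"nb_over_n_{label}": st.nb_over_n})
            if s1 is not None and s3 is not None and s1.admissible and s3.admissible:
                row["pct_change"] = stage_change(s1.r_star, s3.r_star)
            else:
                row["pct_change"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plot analogs (Ne_V histogram; sensitivity curves)
# ---------------------------------------------------------------------------

def plot_ne_histogram(ne_v: np.ndarray, path: Path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(ne_v[np.isfinite(ne_v)], bins=40, color="steelblue", edgecolor="white")
    ax.set_xlabel(r"$N_{eV}$ per replicate")
    ax.set_ylabel("replicates")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sensitivity(grid: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    base_sm = 1.0 if (grid["survival_multiplier"] == 1.0).any() else \
        grid["survival_multiplier"].iloc[0]
    sub = grid[grid["survival_multiplier"] == base_sm]
    axes[0].plot(sub["variance_multiplier"], sub["ne_v_mean"], "o-")
    axes[0].set_xlabel("fecundity variance multiplier")
    axes[0].set_ylabel(r"mean $N_{eV}$")
    base_vm = 1.0 if (grid["variance_multiplier"] == 1.0).any() else \
        grid["variance_multiplier"].iloc[0]
    sub = grid[grid["variance_multiplier"] == base_vm]
    axes[1].plot(sub["survival_multiplier"], sub["ne_v_mean"], "o-")
    axes[1].set_xlabel("survival multiplier")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict, out_dir: str | Path, plots: bool = False) -> dict:
    """Execute the full pipeline from a configuration dict; returns the
    manifest (also written as ``manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    runtimes: dict[str, float] = {}
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": int(config.get("seed", 0)),
        "version": __version__,
        "files": {},
    }

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = out / name
        _write_tsv(df, path)
        written.append(path)
        manifest["files"][name] = {"sha256": _sha256(path), "rows": int(len(df))}
        log.info("wrote %s (%d rows, sha256=%s)", name, len(df),
                 manifest["files"][name]["sha256"][:12])
        return path

    try:
        # -- synthetic data -------------------------------------------------
        t0 = time.perf_counter()
        spec = build_spawner_spec(config)
        spawners = generate_spawners(spec)
        spawners = corrupt_ages(spawners, AgeingErrorModel(),
                                seed=stage_seed(config, "data"))
        fam_specs = build_family_specs(config)
        families = sample_family_sizes(spawners, fam_specs,
                                       seed=stage_seed(config, "data"))
        removal_cfg = config["synthetic"].get("removal", {})
        p_capture = float(removal_cfg.get("capture_probability", 0.6))
        n_passes = int(removal_cfg.get("n_passes", 3))
        removal_rows = []
        rem_seed = stage_seed(config, "data")
        for i, (season, sub) in enumerate(spawners.groupby("season")):
            for j, sex in enumerate(("M", "F")):
                n_true = int((sub["sex"] == sex).sum())
                catches = sample_removal_counts(
                    RemovalSpec(n_true, p_capture, n_passes),
                    seed=(rem_seed + 97 * i + 13 * j) % (2 ** 31))
                removal_rows.append({"season": season, "sex": sex,
                                     **{f"pass{k + 1}": int(c)
                                        for k, c in enumerate(catches)}})
        removals = pd.DataFrame(removal_rows)
        emit("spawners.tsv", spawners)
        emit("families.tsv", families)
        emit("removals.tsv", removals)
        runtimes["simulate_data"] = time.perf_counter() - t0

        # -- census ---------------------------------------------------------
        t0 = time.perf_counter()
        census = estimate_census(removals)
        emit("census.tsv", census)
        runtimes["census"] = time.perf_counter() - t0

        # -- seasonal Nb ----------------------------------------------------
        t0 = time.perf_counter()
        table1 = build_table1(families, census,
                              n_boot=int(config["bootstrap"]["n_boot"]),
                              seed=stage_seed(config, "nb"))
        emit("table1.tsv", table1)
        runtimes["nb"] = time.perf_counter() - t0

        # -- family variance ------------------------------------------------
        t0 = time.perf_counter()
        table2 = build_table2(families, census)
        emit("table2.tsv", table2)
        runtimes["family_variance"] = time.perf_counter() - t0

        # -- iteroparity summary ---------------------------------------------
        emit("iteroparity.tsv", describe_iteroparity(spawners))

        # -- lifetime simulation ---------------------------------------------
        t0 = time.perf_counter()
        life = config["lifetime"]
        result = simulate_lifetimes(
            curve=build_curve(config), survival=build_survival(config),
            fecundity=build_fecundity(config),
            n_males=int(life["n_males"]), n_females=int(life["n_females"]),
            mode=life.get("mode", "iteroparous"),
            n_boot=int(life["n_boot"]), seed=stage_seed(config, "lifetime"),
            census_size=life.get("census_size"),
            gen_length=life.get("gen_length"))
        emit("nev_replicates.tsv", result.replicate_frame())
        runtimes["lifetime"] = time.perf_counter() - t0
        if plots:
            plot_ne_histogram(result.ne_v, out / "nev_histogram.png",
                              title=f"{result.mode} model")
    except Exception:
        for path in written:
            path.rename(path.with_suffix(path.suffix + ".partial"))
        raise

    manifest["runtimes_s"] = {k: round(v, 4) for k, v in runtimes.items()}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
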