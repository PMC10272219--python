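"""End-to-end orchestration: simulate/ingest -> filter -> metrics ->
co-occurrence -> networks -> ordination, with a JSON run manifest.

Stage randomness is derived from a single top-level seed via keyed streams
(see :mod:`herbivar._rng`), so toggling one stage never shifts another's
draws and identical configs reproduce byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .census import Census, aggregate, filter_quarries, read_census, write_catalog, write_census
from .community import anosim, bray_curtis, composition_table, nmds
from .cooccurrence import cooccurrence_matrix, pairing_summary
from .metrics import metrics_table
from .networks import METRIC_NAMES, bootstrap_networks, degree_profile
from .synthetic import SimConfig, default_study_config, generate_census

__all__ = ["RunConfig", "run_pipeline", "outbreak_experiment"]


@dataclass
class RunConfig:
    """Parameters of one full pipeline run."""

    out_dir: str
    seed: int = 0
    census_path: str | None = None  # mutually exclusive with sim_config
    catalog_path: str | None = None
    sim_config: SimConfig | None = None
    n_std: int = 300
    min_leaves: int = 300
    sample_size: int = 300
    n_boot: int = 500
    alpha: float = 0.05
    min_expected: float = 1.0
    drop_singletons: bool = True
    nmds_restarts: int = 20
    n_perm: int = 999
    stages: tuple[str, ...] = ("metrics", "cooccur", "networks", "ordination")


def _load_input(config: RunConfig) -> Census:
    if config.sim_config is not None:
        return generate_census(config.sim_config)
    if config.census_path is None or config.catalog_path is None:
        raise ValueError("RunConfig needs census_path+catalog_path or sim_config")
    return read_census(config.census_path, config.catalog_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "sim_config"
        },
        "stages": {},
    }

    census = _load_input(config)
    write_census(census, out / "census.csv")
    write_catalog(census.catalog, out / "catalog.csv")
    manifest["stages"]["ingest"] = {
        "n_leaves": census.n_leaves, "n_quarries": len(census.quarry_keys)
    }

    filtered, report = filter_quarries(census, config.min_leaves)
    manifest["stages"]["filter"] = {
        "min_leaves": report.min_leaves,
        "removed": {"/".join(k): v for k, v in report.removed.items()},
        "n_retained": len(report.retained),
    }

    if "metrics" in config.stages:
        mt = metrics_table(filtered, n_std=config.n_std)
        mt.to_csv(out / "quarry_metrics.csv", index=False)
        manifest["stages"]["metrics"] = {"rows": len(mt), "n_std": config.n_std}

    if "cooccur" in config.stages:
        n_pairs = {}
        summaries = []
        tables = []
        for forest in sorted(filtered.leaves["forest"].unique()):
            pairs, table, effect = cooccurrence_matrix(
                filtered, forest, alpha=config.alpha,
                min_expected=config.min_expected,
                drop_singletons=config.drop_singletons,
            )
            table.insert(0, "forest", forest)
            tables.append(table)
            summ = pairing_summary(pairs)
            summ.insert(0, "forest", forest)
            summaries.append(summ)
            n_pairs[forest] = len(pairs)
        pd.concat(tables, ignore_index=True).to_csv(out / "cooccurrence_pairs.csv", index=False)
        pd.concat(summaries, ignore_index=True).to_csv(out / "cooccurrence_summary.csv", index=False)
        manifest["stages"]["cooccur"] = {"pairs_per_forest": n_pairs}

    if "networks" in config.stages:
        rows = []
        for key, view in aggregate(filtered, "quarry").items():
            br = bootstrap_networks(
                view, sample_size=config.sample_size, n_boot=config.n_boot,
                seed=config.seed,
            )
            mean = br.reps.mean()
            sd = br.reps.std()
            row = {"forest": key[0], "env": key[1], "quarry": key[2],
                   "n_degenerate": br.n_degenerate}
            for m in METRIC_NAMES:
                row[f"{m}_mean"] = mean[m]
                row[f"{m}_sd"] = sd[m]
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "network_bootstrap.csv", index=False)
        degree_profile(filtered, drop_singletons=False).to_csv(out / "degree_profile.csv")
        manifest["stages"]["networks"] = {
            "quarries": len(rows), "sample_size": config.sample_size,
            "n_boot": config.n_boot,
        }

    if "ordination" in config.stages:
        ord_stats = {}
        for mode in ("ffg", "plant"):
            table = composition_table(filtered, mode)
            d = bray_curtis(table)
            ores = nmds(d, k=2, n_restarts=config.nmds_restarts, seed=config.seed)
            coords = ores.coordinates.copy()
            coords.insert(0, "env", table["env"])
            coords.insert(0, "forest", table["forest"])
            coords.to_csv(out / f"nmds_{mode}.csv")
            res = {"stress": ores.stress}
            for grouping, labels in (
                ("forest", table["forest"]), ("env", table["env"])
            ):
                if labels.nunique() < 2:
                    continue
                a = anosim(d, labels, n_perm=config.n_perm, seed=config.seed,
                           grouping=f"{mode}:{grouping}")
                res[f"anosim_R_{grouping}"] = a.R
                res[f"anosim_p_{grouping}"] = a.p
            ord_stats[mode] = res
        pd.DataFrame(ord_stats).T.to_csv(out / "ordination_stats.csv")
        manifest["stages"]["ordination"] = ord_stats

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def outbreak_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    *,
    config_factory=default_study_config,
    sample_size: int = 300,
    n_boot: int = 100,
    which: tuple[str, ...] = ("connectance", "h2prime"),
    target_metric: str = "h2prime",
) -> tuple[pd.DataFrame, dict]:
    """Paired outbreak/control simulation experiment.

    For each of ``n_seeds`` seeds, simulate the study design with and without
    the outbreak (same seed, so plant draws are paired), bootstrap every
    quarry's network, and record per-forest means of the selected metrics
    plus the total damage frequency.  Returns the long table (one row per
    seed x forest x scenario) and a summary dict with the fraction of seeds
    in which the outbreak forest's mean H2' exceeds its control and the
    total-frequency gap.
    """
    from .metrics import damage_frequency

    rows = []
    target_forest = None
    for s in range(n_seeds):
        sim_seed = base_seed * 1009 + s
        for scenario in ("control", "outbreak"):
            cfg = config_factory(outbreak=(scenario == "outbreak"), seed=sim_seed)
            if scenario == "outbreak":
                target_forest = cfg.outbreak.target_forest_id
            census = generate_census(cfg)
            filtered, _ = filter_quarries(census, sample_size)
            for fkey, fview in aggregate(filtered, "forest").items():
                freq = damage_frequency(fview, "total")
                metric_means = {m: [] for m in which}
                for qkey, qview in aggregate(fview, "quarry").items():
                    br = bootstrap_networks(
                        qview, sample_size=sample_size, n_boot=n_boot,
                        seed=sim_seed, which=which,
                    )
                    for m in which:
                        metric_means[m].append(br.reps[m].mean())
                row = {"seed": s, "forest": fkey[0], "scenario": scenario,
                       "freq_total": freq}
                for m in which:
                    row[f"{m}_mean"] = float(pd.Series(metric_means[m]).mean())
                rows.append(row)
    table = pd.DataFrame(rows)

    tf = table[table["forest"] == target_forest].pivot_table(
        index="seed", columns="scenario",
        values=[f"{target_metric}_mean", "freq_total"],
    )
    wins = (
        tf[(f"{target_metric}_mean", "outbreak")]
        > tf[(f"{target_metric}_mean", "control")]
    )
    freq_gap = (
        tf[("freq_total", "outbreak")] - tf[("freq_total", "control")]
    ).abs()
    summary = {
        "target_forest": target_forest,
        "n_seeds": n_seeds,
        "fraction_h2_elevated": float(wins.mean()),
        "mean_abs_freq_gap_pp": float(freq_gap.mean() * 100),
        "max_abs_freq_gap_pp": float(freq_gap.max() * 100),
    }
    return table, summary
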