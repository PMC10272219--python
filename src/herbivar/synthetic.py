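"""Synthetic leaf-census generator.

Emulates the statistical structure of a multi-forest leaf-litter herbivory
census: a hierarchy of forests, depositional environments and replicate
quarries (~400 leaves each); forest-specific plant pools with the tropical
pool disjoint from the temperate ones; damage types (DTs) with configurable
host breadth (generalist vs specialist), per-leaf occurrence probability and
zero-truncated-Poisson incident counts; and an optional insect-outbreak
scenario that concentrates a small set of surface/hole DTs on one or two
preferred host taxa, emulating a *Lymantria dispar*-type feeding outbreak.

Plant composition is hierarchical-Dirichlet: each environment draws its
composition around the forest pool (concentration ``env_shift``), and each
quarry re-draws more tightly around its environment (``quarry_shift``), so
quarries within an environment are compositionally closer to each other than
to other environments — the structure ordination/ANOSIM should detect.

Everything is deterministic given ``SimConfig.seed``: each (stage, forest,
env, quarry, DT) gets its own derived stream, so host sets are fixed per
(forest, DT) and adding a quarry never shifts another quarry's draws.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from ._rng import derive_rng
from .census import FFGS, Census, CensusValidationError, DTCatalog

__all__ = [
    "EnvSpec",
    "ForestSpec",
    "DTSpec",
    "OutbreakSpec",
    "SimConfig",
    "generate_census",
    "default_study_config",
    "load_config",
    "save_config",
]


@dataclass
class EnvSpec:
    """One depositional environment within a forest.

    ``leaves_per_quarry`` may be a single int (all quarries equal) or a list
    with one entry per quarry.  ``env_shift`` is the Dirichlet concentration
    of the environment-level composition around the forest pool: larger means
    closer to the forest-wide composition.
    """

    env_id: str
    n_quarries: int
    leaves_per_quarry: int | list[int]
    env_shift: float = 10.0

    def quarry_sizes(self) -> list[int]:
        if isinstance(self.leaves_per_quarry, int):
            return [self.leaves_per_quarry] * self.n_quarries
        if len(self.leaves_per_quarry) != self.n_quarries:
            raise CensusValidationError(
                f"env {self.env_id}: leaves_per_quarry list length "
                f"{len(self.leaves_per_quarry)} != n_quarries {self.n_quarries}"
            )
        return [int(v) for v in self.leaves_per_quarry]


@dataclass
class ForestSpec:
    forest_id: str
    plant_pool: dict[str, float]  # taxon -> relative-abundance weight
    envs: list[EnvSpec]
    quarry_shift: float = 150.0  # quarry-level Dirichlet concentration (tighter)

    def validate(self) -> None:
        if not self.plant_pool:
            raise CensusValidationError(f"forest {self.forest_id}: empty plant pool")
        if any(w <= 0 for w in self.plant_pool.values()):
            raise CensusValidationError(
                f"forest {self.forest_id}: plant weights must be positive"
            )
        if not self.envs:
            raise CensusValidationError(f"forest {self.forest_id}: no environments")
        for e in self.envs:
            if e.n_quarries < 1 or any(n < 1 for n in e.quarry_sizes()):
                raise CensusValidationError(
                    f"forest {self.forest_id}/{e.env_id}: quarry counts/sizes must be >= 1"
                )
            if e.env_shift <= 0:
                raise CensusValidationError("env_shift must be positive")


@dataclass
class DTSpec:
    """One damage type's generative parameters.

    host_breadth
        Fraction of each forest's plant pool the DT can occur on; the host
        set is a fixed pseudo-random subset per (forest, DT).
    base_occurrence_prob
        Per-leaf Bernoulli probability on a permitted host.
    abundance_mean
        Rate (lambda) of the Poisson whose zero-truncation gives the incident
        count once the DT occurs on a leaf.
    """

    dt_code: str
    ffg: str
    spec_class: str
    host_breadth: float
    base_occurrence_prob: float
    abundance_mean: float = 1.5

    def validate(self) -> None:
        if self.ffg not in FFGS:
            raise CensusValidationError(f"{self.dt_code}: unknown FFG {self.ffg!r}")
        if self.spec_class not in ("generalized", "specialized"):
            raise CensusValidationError(f"{self.dt_code}: bad spec_class {self.spec_class!r}")
        if not 0 < self.host_breadth <= 1:
            raise CensusValidationError(f"{self.dt_code}: host_breadth must be in (0, 1]")
        if not 0 <= self.base_occurrence_prob <= 1:
            raise CensusValidationError(f"{self.dt_code}: occurrence prob outside [0, 1]")
        if self.abundance_mean <= 0:
            raise CensusValidationError(f"{self.dt_code}: abundance_mean must be > 0")


@dataclass
class OutbreakSpec:
    """Elevated occurrence of a DT set concentrated on preferred hosts."""

    target_forest_id: str
    outbreak_dts: list[str]
    preferred_hosts: list[str]
    occurrence_multiplier: float = 12.0
    background_multiplier: float = 2.0

    def validate(self, forests: Sequence[ForestSpec], dt_pool: Sequence[DTSpec]) -> None:
        forest = {f.forest_id: f for f in forests}.get(self.target_forest_id)
        if forest is None:
            raise CensusValidationError(
                f"outbreak target forest {self.target_forest_id!r} not configured"
            )
        pool_dts = {d.dt_code for d in dt_pool}
        missing = set(self.outbreak_dts) - pool_dts
        if missing:
            raise CensusValidationError(f"outbreak DTs not in pool: {sorted(missing)}")
        missing_hosts = set(self.preferred_hosts) - set(forest.plant_pool)
        if missing_hosts:
            raise CensusValidationError(
                f"preferred hosts absent from {self.target_forest_id}'s pool: "
                f"{sorted(missing_hosts)}"
            )
        if not self.occurrence_multiplier > self.background_multiplier >= 1:
            raise CensusValidationError(
                "need occurrence_multiplier > background_multiplier >= 1"
            )


@dataclass
class SimConfig:
    """Full generative specification of a synthetic multi-forest study."""

    seed: int
    forests: list[ForestSpec]
    dt_pool: list[DTSpec]
    outbreak: OutbreakSpec | None = None
    #: occurrence multiplier (<1) on piercing-and-sucking DTs, reflecting
    #: their preservation bias in sediment-derived leaf assemblages.
    preservation_discount: float = 0.5

    def validate(self) -> None:
        if not self.forests:
            raise CensusValidationError("need at least one forest")
        ids = [f.forest_id for f in self.forests]
        if len(set(ids)) != len(ids):
            raise CensusValidationError("duplicate forest ids")
        for f in self.forests:
            f.validate()
        if not self.dt_pool:
            raise CensusValidationError("empty DT pool")
        codes = [d.dt_code for d in self.dt_pool]
        if len(set(codes)) != len(codes):
            raise CensusValidationError("duplicate DT codes in pool")
        for d in self.dt_pool:
            d.validate()
        if not 0 < self.preservation_discount <= 1:
            raise CensusValidationError("preservation_discount must be in (0, 1]")
        if self.outbreak is not None:
            self.outbreak.validate(self.forests, self.dt_pool)

    def catalog(self) -> DTCatalog:
        return DTCatalog.from_dict(
            {d.dt_code: {"ffg": d.ffg, "spec_class": d.spec_class} for d in self.dt_pool}
        )


# -- sampling helpers ---------------------------------------------------------


def _zero_truncated_poisson(u: np.ndarray, lam: float) -> np.ndarray:
    """Exact zero-truncated Poisson draws via inverse-CDF on the conditioned law."""
    if len(u) == 0:
        return np.zeros(0, dtype=np.int64)
    p0 = math.exp(-lam)
    # P(X <= k | X > 0) maps back to the unconditional CDF targets below.
    target = p0 + u * (1.0 - p0)
    # guard against target == 1.0 rounding issues
    target = np.clip(target, p0, np.nextafter(1.0, 0.0))
    return stats.poisson.ppf(target, lam).astype(np.int64)


def _host_set(
    seed: int, forest: ForestSpec, dt: DTSpec
) -> np.ndarray:
    """Fixed pseudo-random host subset for (forest, DT); boolean over pool order."""
    taxa = list(forest.plant_pool)
    k = math.ceil(dt.host_breadth * len(taxa))
    rng = derive_rng(seed, "hosts", forest.forest_id, dt.dt_code)
    idx = rng.choice(len(taxa), size=k, replace=False)
    mask = np.zeros(len(taxa), dtype=bool)
    mask[idx] = True
    return mask


def generate_census(config: SimConfig) -> Census:
    """Sample a full census from ``config``; deterministic given its seed."""
    config.validate()
    seed = config.seed
    catalog = config.catalog()

    leaf_rows = []  # (leaf_id, forest, env, quarry, plant_taxon)
    inc_rows = []  # (leaf_id, dt_code, count)

    for forest in config.forests:
        taxa = np.array(list(forest.plant_pool))
        w = np.array(list(forest.plant_pool.values()), dtype=float)
        w = w / w.sum()
        host_masks = {
            dt.dt_code: _host_set(seed, forest, dt) for dt in config.dt_pool
        }
        outbreak = config.outbreak
        is_target = outbreak is not None and outbreak.target_forest_id == forest.forest_id
        preferred = (
            np.isin(taxa, outbreak.preferred_hosts) if is_target else np.zeros(len(taxa), bool)
        )

        for env in forest.envs:
            env_rng = derive_rng(seed, "env-comp", forest.forest_id, env.env_id)
            env_comp = env_rng.dirichlet(env.env_shift * w)
            for qi, n_leaves in enumerate(env.quarry_sizes()):
                quarry_id = f"Q{qi + 1}"
                rng = derive_rng(seed, "quarry", forest.forest_id, env.env_id, quarry_id)
                alpha = forest.quarry_shift * env_comp
                # Dirichlet with tiny concentrations can underflow to exact 0
                quarry_comp = rng.dirichlet(np.maximum(alpha, 1e-9))
                leaf_taxon_idx = rng.choice(len(taxa), size=n_leaves, p=quarry_comp)
                leaf_ids = [
                    f"{forest.forest_id}-{env.env_id}-{quarry_id}-L{i + 1:04d}"
                    for i in range(n_leaves)
                ]
                for lid, ti in zip(leaf_ids, leaf_taxon_idx):
                    leaf_rows.append(
                        (lid, forest.forest_id, env.env_id, quarry_id, taxa[ti])
                    )

                for dt in config.dt_pool:
                    permitted = host_masks[dt.dt_code][leaf_taxon_idx]
                    if not permitted.any():
                        continue
                    p = np.full(n_leaves, dt.base_occurrence_prob)
                    if dt.ffg == "piercing_sucking":
                        p *= config.preservation_discount
                    if is_target and dt.dt_code in outbreak.outbreak_dts:
                        mult = np.where(
                            preferred[leaf_taxon_idx],
                            outbreak.occurrence_multiplier,
                            outbreak.background_multiplier,
                        )
                        p = p * mult
                    p = np.clip(p * permitted, 0.0, 1.0)
                    # each DT consumes a fixed number of uniforms per quarry
                    # regardless of p, so same-seed runs that differ only in
                    # occurrence rates (e.g. outbreak vs control) stay coupled
                    occ = rng.random(n_leaves) < p
                    count_u = rng.random(n_leaves)
                    n_occ = int(occ.sum())
                    if n_occ == 0:
                        continue
                    counts = _zero_truncated_poisson(count_u[occ], dt.abundance_mean)
                    for li, c in zip(np.nonzero(occ)[0], counts):
                        inc_rows.append((leaf_ids[li], dt.dt_code, int(c)))

    import pandas as pd

    leaves = pd.DataFrame(
        leaf_rows, columns=["leaf_id", "forest", "env", "quarry", "plant_taxon"]
    ).set_index("leaf_id")
    incidents = pd.DataFrame(inc_rows, columns=["leaf_id", "dt_code", "count"])
    if incidents.empty:
        incidents = incidents.astype({"count": np.int64})
    return Census(leaves, incidents, catalog)


# -- the packaged study design ------------------------------------------------

_TEMPERATE_INLAND_POOL = {
    "Tsuga canadensis": 0.24,
    "Quercus rubra": 0.21,
    "Acer rubrum": 0.17,
    "Fagus grandifolia": 0.14,
    "Betula lenta": 0.10,
    "Betula alleghaniensis": 0.06,
    "Pinus strobus": 0.05,
    "Hamamelis virginiana": 0.03,
}

_TEMPERATE_COASTAL_POOL = {
    "Fagus grandifolia": 0.18,
    "Liquidambar styraciflua": 0.15,
    "Liriodendron tulipifera": 0.13,
    "Quercus alba": 0.11,
    "Quercus rubra": 0.09,
    "Carya alba": 0.08,
    "Cornus florida": 0.06,
    "Acer rubrum": 0.06,
    "Nyssa sylvatica": 0.04,
    "Ulmus americana": 0.03,
    "Carpinus caroliniana": 0.03,
    "Platanus occidentalis": 0.02,
    "Ilex opaca": 0.01,
    "Asimina triloba": 0.01,
}

# Disjoint from the temperate pools by construction (wet-tropical flora).
_TROPICAL_TAXA = [
    "Castilla elastica", "Ficus insipida", "Luehea seemannii",
    "Terminalia oblonga", "Zygia longifolia", "Pentaclethra macroloba",
    "Ceiba pentandra", "Carapa guianensis", "Dipteryx panamensis",
    "Virola koschnyi", "Goethalsia meiantha", "Hernandia didymantha",
    "Trophis racemosa", "Inga alba", "Inga pezizifera",
    "Protium ravenii", "Socratea exorrhiza", "Welfia regia",
    "Cecropia obtusifolia", "Simarouba amara", "Laetia procera",
    "Miconia affinis", "Guarea guidonia", "Brosimum lactescens",
    "Apeiba membranacea",
]

# (ffg, n_generalized, n_specialized) composition of the packaged DT pool.
_DT_DESIGN = [
    ("hole", 6, 2),
    ("margin", 5, 1),
    ("skeletonization", 3, 1),
    ("surface", 5, 2),
    ("piercing_sucking", 3, 2),
    ("gall", 1, 7),
    ("mine", 0, 7),
]


def _default_dt_pool() -> list[DTSpec]:
    """Fixed 45-DT pool spanning the seven FFGs.

    Parameters cycle deterministically (no RNG): generalists get broad host
    ranges (0.7-1.0) and moderate occurrence; specialists narrow host ranges
    (~0.08-0.2) and low occurrence.  Aggregate per-leaf expected occurrences
    come to ~1.3, i.e. total damage frequencies around 65-75%.
    """
    pool: list[DTSpec] = []
    code = 0
    for ffg, n_gen, n_spec in _DT_DESIGN:
        for i in range(n_gen):
            code += 1
            pool.append(
                DTSpec(
                    dt_code=f"DT{code}",
                    ffg=ffg,
                    spec_class="generalized",
                    host_breadth=0.7 + 0.1 * (i % 4),
                    base_occurrence_prob=0.02 + 0.025 * (i % 5),
                    abundance_mean=1.0 + 0.4 * (i % 4),
                )
            )
        for i in range(n_spec):
            code += 1
            pool.append(
                DTSpec(
                    dt_code=f"DT{code}",
                    ffg=ffg,
                    spec_class="specialized",
                    host_breadth=0.08 + 0.04 * (i % 4),
                    base_occurrence_prob=0.01 + 0.015 * (i % 4),
                    abundance_mean=1.0 + 0.3 * (i % 3),
                )
            )
    return pool


def default_study_config(outbreak: bool = False, seed: int = 0) -> SimConfig:
    """The packaged three-forest study design.

    One temperate-inland forest (smallest plant pool; 3 environments x 3
    quarries plus a single upland quarry), one temperate-coastal and one
    wet-tropical forest (3 environments x 3 quarries each); 400 leaves per
    quarry, 28 quarries, 11,200 leaves.  The tropical pool shares no species
    with the temperate pools.  With ``outbreak=True`` a surface DT and a hole
    DT are elevated on one preferred host (*Quercus rubra*) in the
    temperate-inland forest; the configs differ in nothing else.
    """
    std_envs = lambda: [
        EnvSpec("swamp", 3, 400, env_shift=10.0),
        EnvSpec("tributary", 3, 400, env_shift=10.0),
        EnvSpec("river", 3, 400, env_shift=10.0),
    ]
    forests = [
        ForestSpec(
            "temperate_inland",
            dict(_TEMPERATE_INLAND_POOL),
            std_envs() + [EnvSpec("upland", 1, 400, env_shift=10.0)],
        ),
        ForestSpec("temperate_coastal", dict(_TEMPERATE_COASTAL_POOL), std_envs()),
        ForestSpec(
            "tropical",
            {t: 1.0 / (r + 2) for r, t in enumerate(_TROPICAL_TAXA)},
            std_envs(),
        ),
    ]
    pool = _default_dt_pool()
    ob = None
    if outbreak:
        surface_gen = next(d for d in pool if d.ffg == "surface" and d.spec_class == "generalized")
        hole_gen = next(d for d in pool if d.ffg == "hole" and d.spec_class == "generalized")
        ob = OutbreakSpec(
            target_forest_id="temperate_inland",
            outbreak_dts=[surface_gen.dt_code, hole_gen.dt_code],
            preferred_hosts=["Quercus rubra"],
            occurrence_multiplier=12.0,
            background_multiplier=2.0,
        )
    return SimConfig(seed=seed, forests=forests, dt_pool=pool, outbreak=ob)


# -- config (de)serialization -------------------------------------------------


def save_config(config: SimConfig, path: str | Path) -> None:
    data = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    forests = [
        ForestSpec(
            forest_id=f["forest_id"],
            plant_pool=f["plant_pool"],
            envs=[EnvSpec(**e) for e in f["envs"]],
            quarry_shift=f.get("quarry_shift", 150.0),
        )
        for f in data["forests"]
    ]
    pool = [DTSpec(**d) for d in data["dt_pool"]]
    ob = OutbreakSpec(**data["outbreak"]) if data.get("outbreak") else None
    cfg = SimConfig(
        seed=data["seed"],
        forests=forests,
        dt_pool=pool,
        outbreak=ob,
        preservation_discount=data.get("preservation_discount", 0.5),
    )
    cfg.validate()
    return cfg
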