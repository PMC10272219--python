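"""Leaf-census data model, validation and CSV I/O.

A census is a hierarchical collection of leaves (forest > depositional
environment > quarry > leaf), each leaf carrying a plant-taxon assignment and a
map of damage-type (DT) incident counts.  Occurrence of a DT on a leaf is
presence of the key; abundance is the incident count (>= 1).  Undamaged leaves
are first-class citizens: they carry an empty count map and must be present so
damage frequencies have per-leaf-censused denominators.

The canonical interchange format is a long (tidy) CSV with one row per
(leaf, DT) incident group and one row per undamaged leaf (empty dt_code/count):

    leaf_id,forest,depositional_environment,quarry,plant_taxon,dt_code,count

A companion catalog CSV maps each DT code to its functional feeding group
(FFG) and generalized/specialized class:

    dt_code,ffg,spec_class
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FFGS",
    "SPEC_CLASSES",
    "CensusValidationError",
    "DTCatalog",
    "LeafRecord",
    "Census",
    "ExclusionReport",
    "read_census",
    "write_census",
    "read_catalog",
    "write_catalog",
    "filter_quarries",
    "aggregate",
]

#: The seven functional feeding groups of the damage-type system.
FFGS = (
    "hole",
    "margin",
    "skeletonization",
    "surface",
    "piercing_sucking",
    "gall",
    "mine",
)

SPEC_CLASSES = ("generalized", "specialized")

CENSUS_COLUMNS = (
    "leaf_id",
    "forest",
    "depositional_environment",
    "quarry",
    "plant_taxon",
    "dt_code",
    "count",
)

CATALOG_COLUMNS = ("dt_code", "ffg", "spec_class")


class CensusValidationError(ValueError):
    """Raised when a census or catalog violates a structural invariant."""


@dataclass(frozen=True)
class DTCatalog:
    """Damage-type catalog: DT code -> FFG and generalized/specialized class.

    Parameters
    ----------
    table
        DataFrame indexed by dt_code with columns ``ffg`` and ``spec_class``.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if list(t.columns) != ["ffg", "spec_class"]:
            raise CensusValidationError(
                f"catalog columns must be ['ffg', 'spec_class'], got {list(t.columns)}"
            )
        if t.index.has_duplicates:
            dupes = sorted(t.index[t.index.duplicated()].unique())
            raise CensusValidationError(f"duplicate dt_code in catalog: {dupes}")
        bad_ffg = sorted(set(t["ffg"]) - set(FFGS))
        if bad_ffg:
            raise CensusValidationError(
                f"unknown FFG categories {bad_ffg}; allowed: {list(FFGS)}"
            )
        bad_cls = sorted(set(t["spec_class"]) - set(SPEC_CLASSES))
        if bad_cls:
            raise CensusValidationError(
                f"unknown spec_class values {bad_cls}; allowed: {list(SPEC_CLASSES)}"
            )

    @classmethod
    def from_dict(cls, entries: Mapping[str, Mapping[str, str]]) -> "DTCatalog":
        """Build from ``{dt_code: {"ffg": ..., "spec_class": ...}}``."""
        table = pd.DataFrame.from_dict(dict(entries), orient="index")[
            ["ffg", "spec_class"]
        ]
        table.index.name = "dt_code"
        return cls(table)

    @property
    def dt_codes(self) -> list[str]:
        return list(self.table.index)

    def ffg_of(self, dt_code: str) -> str:
        return self.table.at[dt_code, "ffg"]

    def spec_class_of(self, dt_code: str) -> str:
        return self.table.at[dt_code, "spec_class"]

    def resolve_selector(self, selector: str) -> frozenset[str] | None:
        """Translate a metric selector into a DT-code set.

        ``"total"`` -> None (all DTs); ``"generalized"``/``"specialized"``
        select by class; an FFG name selects that feeding group.
        """
        if selector == "total":
            return None
        if selector in SPEC_CLASSES:
            mask = self.table["spec_class"] == selector
        elif selector in FFGS:
            mask = self.table["ffg"] == selector
        else:
            raise CensusValidationError(
                f"unresolvable selector {selector!r}; use 'total', a spec class "
                f"{list(SPEC_CLASSES)} or an FFG {list(FFGS)}"
            )
        return frozenset(self.table.index[mask])


@dataclass(frozen=True)
class LeafRecord:
    """One censused leaf with its hierarchy and DT incident counts."""

    leaf_id: str
    forest_id: str
    env_id: str
    quarry_id: str
    plant_taxon: str
    dt_abundances: Mapping[str, int] = field(default_factory=dict)

    @property
    def damaged(self) -> bool:
        return len(self.dt_abundances) > 0


class Census:
    """A validated leaf census: leaf table + incident table + DT catalog.

    Internally two DataFrames are held: ``leaves`` (index leaf_id; columns
    forest, env, quarry, plant_taxon) and ``incidents`` (columns leaf_id,
    dt_code, count).  All downstream modules consume this type only.
    """

    def __init__(
        self,
        leaves: pd.DataFrame,
        incidents: pd.DataFrame,
        catalog: DTCatalog,
        *,
        validate: bool = True,
    ):
        self.leaves = leaves
        self.incidents = incidents.reset_index(drop=True)
        self.catalog = catalog
        if validate:
            self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[LeafRecord], catalog: DTCatalog) -> "Census":
        rows, inc = [], []
        for r in records:
            rows.append((r.leaf_id, r.forest_id, r.env_id, r.quarry_id, r.plant_taxon))
            for dt, n in r.dt_abundances.items():
                inc.append((r.leaf_id, dt, int(n)))
        leaves = pd.DataFrame(
            rows, columns=["leaf_id", "forest", "env", "quarry", "plant_taxon"]
        ).set_index("leaf_id")
        incidents = pd.DataFrame(inc, columns=["leaf_id", "dt_code", "count"])
        if incidents.empty:
            incidents = incidents.astype({"count": np.int64})
        return cls(leaves, incidents, catalog)

    def _validate(self) -> None:
        if self.leaves.index.has_duplicates:
            dupes = sorted(self.leaves.index[self.leaves.index.duplicated()].unique())
            raise CensusValidationError(f"duplicate leaf_id: {dupes[:10]}")
        if len(self.leaves) == 0:
            raise CensusValidationError("census contains no leaves")
        for col in ("forest", "env", "quarry"):
            empty = self.leaves[col].isna() | (self.leaves[col].astype(str) == "")
            if empty.any():
                raise CensusValidationError(
                    f"empty {col} for leaves {list(self.leaves.index[empty][:10])}"
                )
        if not self.incidents.empty:
            unknown_leaf = set(self.incidents["leaf_id"]) - set(self.leaves.index)
            if unknown_leaf:
                raise CensusValidationError(
                    f"incidents reference unknown leaf ids: {sorted(unknown_leaf)[:10]}"
                )
            bad = self.incidents["count"] <= 0
            if bad.any():
                raise CensusValidationError(
                    "non-positive incident counts for rows "
                    f"{self.incidents.loc[bad, ['leaf_id', 'dt_code']].values.tolist()[:10]}"
                )
            unknown_dt = sorted(set(self.incidents["dt_code"]) - set(self.catalog.dt_codes))
            if unknown_dt:
                raise CensusValidationError(
                    f"dt_code(s) absent from catalog: {unknown_dt}"
                )
            if self.incidents.duplicated(subset=["leaf_id", "dt_code"]).any():
                raise CensusValidationError(
                    "duplicate (leaf_id, dt_code) incident rows; sum them on ingest"
                )

    # -- basic queries -------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def quarry_keys(self) -> list[tuple[str, str, str]]:
        """Sorted (forest, env, quarry) triples present in the census."""
        key = self.leaves[["forest", "env", "quarry"]].drop_duplicates()
        return sorted(map(tuple, key.itertuples(index=False)))

    def quarry_sizes(self) -> pd.Series:
        """Leaf count per (forest, env, quarry)."""
        return self.leaves.groupby(["forest", "env", "quarry"]).size()

    def iter_leaves(self) -> Iterator[LeafRecord]:
        by_leaf: dict[str, dict[str, int]] = {}
        for lid, dt, n in self.incidents.itertuples(index=False):
            by_leaf.setdefault(lid, {})[dt] = int(n)
        for lid, row in self.leaves.iterrows():
            yield LeafRecord(
                leaf_id=lid,
                forest_id=row["forest"],
                env_id=row["env"],
                quarry_id=row["quarry"],
                plant_taxon=row["plant_taxon"],
                dt_abundances=by_leaf.get(lid, {}),
            )

    def occurrence_matrix(self, dt_codes: list[str] | None = None) -> pd.DataFrame:
        """Binary leaf x DT occurrence matrix (all leaves, damaged or not)."""
        if dt_codes is None:
            dt_codes = sorted(set(self.incidents["dt_code"]))
        mat = pd.DataFrame(
            0, index=self.leaves.index, columns=dt_codes, dtype=np.int8
        )
        inc = self.incidents[self.incidents["dt_code"].isin(dt_codes)]
        if not inc.empty:
            mat.values[
                mat.index.get_indexer(inc["leaf_id"]),
                mat.columns.get_indexer(inc["dt_code"]),
            ] = 1
        return mat

    def subset(self, leaf_ids) -> "Census":
        """A view-census restricted to ``leaf_ids`` (no revalidation needed)."""
        leaf_ids = pd.Index(leaf_ids)
        leaves = self.leaves.loc[leaf_ids]
        incidents = self.incidents[self.incidents["leaf_id"].isin(set(leaf_ids))]
        return Census(leaves, incidents, self.catalog, validate=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Census):
            return NotImplemented
        a = self.incidents.sort_values(["leaf_id", "dt_code"]).reset_index(drop=True)
        b = other.incidents.sort_values(["leaf_id", "dt_code"]).reset_index(drop=True)
        return (
            self.leaves.sort_index().equals(other.leaves.sort_index())
            and a.equals(b)
            and self.catalog.table.sort_index().equals(other.catalog.table.sort_index())
        )

    def __repr__(self) -> str:
        return (
            f"Census({self.n_leaves} leaves, {len(self.quarry_keys)} quarries, "
            f"{len(set(self.incidents['dt_code'])) if not self.incidents.empty else 0} DTs)"
        )


# -- I/O ---------------------------------------------------------------------


def read_catalog(path: str | Path) -> DTCatalog:
    df = pd.read_csv(path, dtype=str)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise CensusValidationError(f"catalog file missing columns {sorted(missing)}")
    return DTCatalog(df.set_index("dt_code")[["ffg", "spec_class"]])


def write_catalog(catalog: DTCatalog, path: str | Path) -> None:
    catalog.table.reset_index().to_csv(path, index=False)


def read_census(path: str | Path, catalog_path: str | Path) -> Census:
    """Read a long-format census CSV plus its DT catalog.

    Rows sharing (leaf_id, dt_code) are summed; rows with empty dt_code are
    undamaged leaves and are retained with empty abundance maps.  Conflicting
    hierarchy or taxon values for one leaf id are a validation error.
    """
    catalog = read_catalog(catalog_path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(CENSUS_COLUMNS) - set(df.columns)
    if missing:
        raise CensusValidationError(f"census file missing columns {sorted(missing)}")

    meta = df[["leaf_id", "forest", "depositional_environment", "quarry", "plant_taxon"]]
    meta = meta.drop_duplicates()
    if meta["leaf_id"].duplicated().any():
        bad = sorted(meta["leaf_id"][meta["leaf_id"].duplicated()].unique())
        raise CensusValidationError(
            f"leaf id(s) with conflicting hierarchy/taxon across rows: {bad[:10]}"
        )
    leaves = meta.rename(columns={"depositional_environment": "env"}).set_index("leaf_id")

    damaged = df[df["dt_code"] != ""].copy()
    if (damaged["count"] == "").any():
        bad = damaged.loc[damaged["count"] == "", "leaf_id"].tolist()
        raise CensusValidationError(f"dt_code present but count empty for leaves {bad[:10]}")
    damaged["count"] = pd.to_numeric(damaged["count"])
    if (damaged["count"] <= 0).any() or not np.allclose(
        damaged["count"], damaged["count"].astype(int)
    ):
        raise CensusValidationError("incident counts must be positive integers")
    damaged["count"] = damaged["count"].astype(np.int64)
    incidents = (
        damaged.groupby(["leaf_id", "dt_code"], as_index=False)["count"].sum()
    )
    return Census(leaves, incidents, catalog)


def write_census(census: Census, path: str | Path) -> None:
    """Write the long-format CSV (inverse of :func:`read_census`)."""
    leaves = census.leaves.reset_index()
    inc = census.incidents
    merged = leaves.merge(inc, on="leaf_id", how="left")
    merged["dt_code"] = merged["dt_code"].fillna("")
    merged["count"] = merged["count"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    merged = merged.rename(columns={"env": "depositional_environment"})
    merged = merged[list(CENSUS_COLUMNS)].sort_values(["leaf_id", "dt_code"])
    merged.to_csv(path, index=False)


# -- filtering and aggregation ----------------------------------------------


@dataclass(frozen=True)
class ExclusionReport:
    """Quarries removed by a minimum-leaf-count filter."""

    min_leaves: int
    removed: dict[tuple[str, str, str], int]  # quarry key -> leaf count
    retained: dict[tuple[str, str, str], int]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_quarries(
    census: Census, min_leaves: int = 300
) -> tuple[Census, ExclusionReport]:
    """Drop quarries with fewer than ``min_leaves`` leaves.

    Mirrors the standard pre-analysis exclusion of under-sampled quarries so
    that rarefaction to ``min_leaves`` and the 300-leaf network bootstrap are
    well defined.  Retained quarries are untouched.
    """
    sizes = census.quarry_sizes()
    removed = {tuple(k): int(v) for k, v in sizes[sizes < min_leaves].items()}
    retained = {tuple(k): int(v) for k, v in sizes[sizes >= min_leaves].items()}
    report = ExclusionReport(min_leaves=min_leaves, removed=removed, retained=retained)
    if not retained:
        raise CensusValidationError(
            f"all {len(removed)} quarries fall below {min_leaves} leaves"
        )
    if not removed:
        return census, report
    keys = census.leaves[["forest", "env", "quarry"]].apply(tuple, axis=1)
    keep = ~keys.isin(set(removed))
    return census.subset(census.leaves.index[keep]), report


def aggregate(census: Census, level: str) -> dict[tuple, Census]:
    """Partition the census at ``level`` in {'quarry', 'env', 'forest'}.

    Returns a dict keyed by (forest,), (forest, env) or (forest, env, quarry);
    values are view-censuses.  Every leaf lands in exactly one group.
    """
    cols = {"forest": ["forest"], "env": ["forest", "env"], "quarry": ["forest", "env", "quarry"]}
    if level not in cols:
        raise CensusValidationError(f"level must be one of {list(cols)}, got {level!r}")
    out: dict[tuple, Census] = {}
    for key, group in census.leaves.groupby(cols[level], sort=True):
        out[tuple(key)] = census.subset(group.index)
    return out
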