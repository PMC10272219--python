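import numpy as np
import pytest

from herbivar.census import Census, DTCatalog, LeafRecord


@pytest.fixture(scope="session")
def small_catalog() -> DTCatalog:
    return DTCatalog.from_dict(
        {
            "DT2": {"ffg": "hole", "spec_class": "generalized"},
            "DT3": {"ffg": "hole", "spec_class": "generalized"},
            "DT12": {"ffg": "margin", "spec_class": "generalized"},
            "DT16": {"ffg": "skeletonization", "spec_class": "generalized"},
            "DT32": {"ffg": "gall", "spec_class": "specialized"},
            "DT37": {"ffg": "mine", "spec_class": "specialized"},
            "DT46": {"ffg": "piercing_sucking", "spec_class": "generalized"},
            "DT333": {"ffg": "surface", "spec_class": "generalized"},
        }
    )


def make_census(leaf_specs, catalog, forest="F1", env="E1", quarry="Q1"):
    """leaf_specs: list of dt->count dicts (one per leaf) or (taxon, dts) tuples."""
    records = []
    for i, spec in enumerate(leaf_specs):
        if isinstance(spec, tuple):
            taxon, dts = spec
        else:
            taxon, dts = "P1", spec
        records.append(
            LeafRecord(
                leaf_id=f"L{i + 1}",
                forest_id=forest,
                env_id=env,
                quarry_id=quarry,
                plant_taxon=taxon,
                dt_abundances=dts,
            )
        )
    return Census.from_records(records, catalog)


@pytest.fixture(scope="session")
def four_leaf_census(small_catalog) -> Census:
    """4 leaves: {A}, {A}, {B}, {} with A=DT2, B=DT3 (the rarefaction fixture)."""
    return make_census(
        [{"DT2": 1}, {"DT2": 2}, {"DT3": 1}, {}], small_catalog
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
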