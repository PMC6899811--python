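import numpy as np
import pandas as pd
import pytest

from mpabias.pipeline import stage_protect, stage_threat
from mpabias.synthetic_world import SyntheticWorld, WorldConfig, generate_world

# a compact world exercising every structural feature (transboundary
# ecoregions, decoy MPA records, missing years)
SMALL = dict(
    n_countries=4,
    n_ecoregions=16,
    transboundary_fraction=0.25,
    grid_cells_per_ecoregion=4,
    n_threat_layers=6,
    n_stoppable_layers=3,
)


def make_world(seed: int = 1, **overrides) -> SyntheticWorld:
    params = {**SMALL, **overrides}
    return generate_world(WorldConfig(seed=seed, **params))


@pytest.fixture(scope="session")
def biased_world() -> SyntheticWorld:
    """Strongly threat-targeting estate with 20% missing years."""
    return make_world(seed=1, bias_beta=2.0, missing_year_fraction=0.2)


@pytest.fixture(scope="session")
def unbiased_world() -> SyntheticWorld:
    return make_world(seed=7, bias_beta=0.0)


def observed_global_impact(world: SyntheticWorld, seed: int = 0,
                           n_sims: int = 1000, ci_mode: str = "percentile",
                           run_null: bool = True) -> pd.Series:
    """Global impact-metric row for a world (threat + protect + impact)."""
    from mpabias.impact_metric import evaluate_impacts

    threat = stage_threat(world)
    protect = stage_protect(world, seed=seed)
    res = evaluate_impacts(
        zone_protection=protect["zone_summary"][("all", 2013)],
        zone_threat=threat["zone_threat"][2013],
        eco_protection=protect["eco_summary"][("all", 2013)],
        eco_threat=threat["eco_threat"][2013],
        mpas=protect["mpas"],
        n_sims=n_sims if run_null else 2,
        seed=seed, ci_mode=ci_mode, include_countries=False,
    )
    return res.iloc[0]


@pytest.fixture()
def toy_grid() -> dict:
    """Two zones, three cells, two layers with hand-checkable values."""
    grid = pd.DataFrame({
        "cell_id": ["x0", "x1", "x2"],
        "country_id": ["A", "A", "B"],
        "ecoregion_id": ["E0", "E0", "E1"],
        "area_km2": [1.0, 1.0, 2.0],
        "f_2008": [1.0, 3.0, 0.0],
        "f_2013": [3.0, 5.0, 0.0],
        "c_2008": [0.0, 10.0, 5.0],
        "c_2013": [0.0, 10.0, 5.0],
    })
    layer_meta = pd.DataFrame({
        "layer_id": ["f", "c"],
        "category": ["fishing_pressure", "climate"],
        "measured_2008": [True, True],
        "measured_2013": [True, True],
    })
    zones = pd.DataFrame({
        "country_id": ["A", "B"],
        "ecoregion_id": ["E0", "E1"],
        "area_km2": [2.0, 2.0],
    })
    return {"grid": grid, "layer_meta": layer_meta, "zones": zones}


def make_mpas(rows) -> pd.DataFrame:
    """Build an MPA table from (id, country, area, category, year) tuples."""
    defaults = dict(status="designated", is_unesco_biosphere=False,
                    has_boundary=True, is_marine=True)
    recs = []
    for mpa_id, country, area, category, year in rows:
        recs.append(dict(mpa_id=mpa_id, country_id=country,
                         total_area_km2=area, iucn_category=category,
                         establishment_year=year, **defaults))
    df = pd.DataFrame(recs)
    df["establishment_year"] = df["establishment_year"].astype("Int64")
    return df
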