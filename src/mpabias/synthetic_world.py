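"""Synthetic worlds: grids, countries, ecoregions, threat layers and MPA estates.

The generator emulates the structure of the global analysis — marine
ecoregions partitioned into country zones inside EEZs, a stack of threat
layers measured in two periods (2008 and 2013), and an MPA estate whose
placement can be biased toward or away from high-threat ecoregions — so that
every downstream stage (zonal statistics, protection accounting, sector
classification, the impact metric and its random-allocation null) can be
tested against known ground truth without any external data.

Placement model
---------------
MPAs are placed by repeatedly drawing an ecoregion with probability
proportional to ``exp(bias_beta * z)``, where ``z`` is the ecoregion's
standardized latent stoppable-threat level, and allocating the drawn MPA's
area into that ecoregion's country zones (capped at remaining capacity).
``bias_beta = 0`` therefore reduces exactly to uniform draws over ecoregions
with replacement — the same law as the random-allocation counterfactual —
while positive (negative) values target (avoid) high-threat ecoregions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "corrupt_years",
    "write_world",
    "read_world",
]

#: stoppable categories cycle through these in generated layer metadata
_STOPPABLE_CATEGORIES = ("fishing_pressure", "fishing_pressure", "fishing_pressure",
                         "benthic_structure", "direct_human")
_UNSTOPPABLE_CATEGORIES = ("climate", "climate", "land_based", "other")

_IUCN_CATEGORIES = np.array(
    ["Ia", "Ib", "II", "III", "IV", "V", "VI",
     "not_applicable", "not_reported", "not_assigned"]
)
# rough mix of strict, sustainable-use and unclassified records
_IUCN_WEIGHTS = np.array([2, 2, 8, 3, 10, 8, 20, 7, 30, 10], dtype=float)
_IUCN_WEIGHTS /= _IUCN_WEIGHTS.sum()


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world.

    Parameters
    ----------
    n_countries, n_ecoregions : int
        Number of countries and of marine ecoregions. Defaults mirror the
        global study scale (232 ecoregions; the 20 countries examined in
        detail).
    transboundary_fraction : float
        Fraction of ecoregions spanning more than one country's EEZ
        (default 0.634, i.e. 147 of 232).
    grid_cells_per_ecoregion : int
        Grid cells per ecoregion; must be at least 3 so transboundary
        ecoregions have at least one cell per member country.
    n_threat_layers, n_stoppable_layers : int
        Total threat layers and how many of them are stoppable
        (fishing pressure / benthic structures / direct human impact).
    threat_distribution_params : mapping period -> (shape, scale)
        Gamma parameters of cell-level threat values; the per-ecoregion
        latent multiplier and a per-layer multiplier scale the ``scale``.
        Defaults give mean 1.0 in 2008 and 1.15 in 2013, so threat grows
        between the periods.
    bias_beta : float
        Placement bias. 0 = random placement (uniform over ecoregions,
        like the counterfactual null); >0 targets high-threat ecoregions;
        <0 avoids them.
    total_protected_fraction_by_period : mapping period -> float
        Cumulative fraction of total marine area protected by the end of
        each period. Defaults 0.043 (2008) and 0.090 (2013): 9.0% of
        national waters protected in 2013, of which 4.7% was added after
        2008.
    missing_year_fraction : float
        Fraction of MPA records whose establishment year is blanked out
        (to be imputed downstream).
    mpa_median_size : float or None
        Median of the lognormal MPA-size distribution, in km². ``None``
        sizes MPAs so the 2013 estate holds ~100 of them.
    mpa_size_sigma : float
        Log-scale sd of MPA sizes; right-skewed, so the median sits
        strictly below the mean (the null model deliberately uses the
        median). The default is small so that an unbiased estate is
        distributed like the fixed-median-size counterfactual null —
        larger dispersion makes the observed estate lumpier than the null
        and over-rejects under random placement.
    transboundary_threat_boost : float
        Multiplier on the latent threat of transboundary ecoregions
        (1.0 = no effect); lets tests build worlds where border-crossing
        ecoregions are systematically more threatened.
    seed : int
        Master seed; all world randomness derives from it.
    """

    n_countries: int = 20
    n_ecoregions: int = 232
    transboundary_fraction: float = 0.634
    grid_cells_per_ecoregion: int = 6
    n_threat_layers: int = 12
    n_stoppable_layers: int = 7
    threat_distribution_params: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {2008: (2.0, 0.5), 2013: (2.0, 0.575)}
    )
    bias_beta: float = 0.0
    total_protected_fraction_by_period: Mapping[int, float] = field(
        default_factory=lambda: {2008: 0.043, 2013: 0.090}
    )
    missing_year_fraction: float = 0.0
    mpa_median_size: float | None = None
    mpa_size_sigma: float = 0.10
    transboundary_threat_boost: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.n_ecoregions < 1:
            raise ValueError("n_countries and n_ecoregions must be positive")
        if not 0.0 <= self.transboundary_fraction <= 1.0:
            raise ValueError("transboundary_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_year_fraction <= 1.0:
            raise ValueError("missing_year_fraction must be in [0, 1]")
        if self.n_stoppable_layers < 1 or self.n_stoppable_layers > self.n_threat_layers:
            raise ValueError("need 1 <= n_stoppable_layers <= n_threat_layers")
        if self.grid_cells_per_ecoregion < 3:
            raise ValueError("grid_cells_per_ecoregion must be >= 3")
        if self.transboundary_fraction > 0 and self.n_countries < 2:
            raise ValueError("transboundary ecoregions require >= 2 countries")
        for period, frac in self.total_protected_fraction_by_period.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"infeasible protection fraction {frac} for period {period}"
                )

    @property
    def n_transboundary(self) -> int:
        return int(round(self.transboundary_fraction * self.n_ecoregions))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["threat_distribution_params"] = {
            int(k): list(v) for k, v in self.threat_distribution_params.items()
        }
        d["total_protected_fraction_by_period"] = {
            int(k): float(v) for k, v in self.total_protected_fraction_by_period.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        d = dict(d)
        if "threat_distribution_params" in d:
            d["threat_distribution_params"] = {
                int(k): tuple(v) for k, v in d["threat_distribution_params"].items()
            }
        if "total_protected_fraction_by_period" in d:
            d["total_protected_fraction_by_period"] = {
                int(k): float(v)
                for k, v in d["total_protected_fraction_by_period"].items()
            }
        return cls(**d)


@dataclass
class SyntheticWorld:
    """A generated world: tabular layers plus the generating ground truth.

    Attributes
    ----------
    grid : DataFrame
        One row per cell: ``cell_id, country_id, ecoregion_id, area_km2``
        and one value column per threat layer per period
        (``<layer_id>_<period>``).
    layer_meta : DataFrame
        ``layer_id, category, measured_2008, measured_2013``.
    zones : DataFrame
        One row per (country, ecoregion) zone: ``country_id, ecoregion_id,
        area_km2``.
    mpas : DataFrame
        One row per MPA record: id, country, total area, IUCN category,
        status, flags and (possibly missing) establishment year.
    allocations : DataFrame
        ``mpa_id, country_id, ecoregion_id, area_km2`` — how each MPA's
        area is split across zones.
    truth : dict
        The generating configuration plus latent per-ecoregion threat and
        the standardized scores that drove placement.
    """

    grid: pd.DataFrame
    layer_meta: pd.DataFrame
    zones: pd.DataFrame
    mpas: pd.DataFrame
    allocations: pd.DataFrame
    truth: dict


def _make_layer_meta(config: WorldConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_threat_layers):
        if i < config.n_stoppable_layers:
            cat = _STOPPABLE_CATEGORIES[i % len(_STOPPABLE_CATEGORIES)]
        else:
            j = i - config.n_stoppable_layers
            cat = _UNSTOPPABLE_CATEGORIES[j % len(_UNSTOPPABLE_CATEGORIES)]
        rows.append({"layer_id": f"layer{i:02d}", "category": cat,
                     "measured_2008": True, "measured_2013": True})
    return pd.DataFrame(rows)


def _assign_ecoregions(config: WorldConfig, rng: np.random.Generator):
    """Country membership per ecoregion; transboundary ones span 2-3 countries."""
    countries = [f"C{i:02d}" for i in range(config.n_countries)]
    n_trans = config.n_transboundary
    trans_ids = set(rng.choice(config.n_ecoregions, size=n_trans, replace=False))
    membership = {}
    for e in range(config.n_ecoregions):
        eco = f"E{e:03d}"
        if e in trans_ids:
            k = 3 if (config.n_countries >= 3 and rng.random() < 0.25) else 2
            members = rng.choice(config.n_countries, size=k, replace=False)
        else:
            members = [rng.integers(config.n_countries)]
        membership[eco] = [countries[int(c)] for c in members]
    return membership


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` by weights, every part >= 1."""
    n = len(weights)
    if total < n:
        raise ValueError("fewer cells than zones")
    raw = weights / weights.sum() * (total - n)
    base = np.floor(raw).astype(int)
    rem = total - n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base + 1


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a reproducible synthetic world from `config`.

    Raises
    ------
    ValueError
        If any period's protection fraction is infeasible (> 1).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_threat, rng_mpa = (np.random.default_rng(s) for s in ss.spawn(3))

    membership = _assign_ecoregions(config, rng_struct)
    ecoregions = sorted(membership)

    # zone areas: log-normal so a few large ecoregions dominate total area
    zone_rows = []
    for eco in ecoregions:
        for c in membership[eco]:
            area = float(rng_struct.lognormal(math.log(1000.0), 1.0))
            zone_rows.append({"country_id": c, "ecoregion_id": eco, "area_km2": area})
    zones = pd.DataFrame(zone_rows).sort_values(
        ["country_id", "ecoregion_id"], ignore_index=True
    )

    # cells: fixed count per ecoregion, split across its zones by area
    cell_rows = []
    cell_counter = 0
    for eco in ecoregions:
        zsub = zones[zones["ecoregion_id"] == eco]
        counts = _largest_remainder(
            zsub["area_km2"].to_numpy(), config.grid_cells_per_ecoregion
        )
        for (_, zrow), k in zip(zsub.iterrows(), counts):
            w = rng_struct.dirichlet(np.full(k, 5.0)) * zrow["area_km2"]
            for a in w:
                cell_rows.append({
                    "cell_id": f"X{cell_counter:05d}",
                    "country_id": zrow["country_id"],
                    "ecoregion_id": eco,
                    "area_km2": float(a),
                })
                cell_counter += 1
    grid = pd.DataFrame(cell_rows)

    layer_meta = _make_layer_meta(config)

    # latent per-ecoregion stoppable threat level (drives both the cell
    # values of stoppable layers and, standardized, the placement bias)
    latent = pd.Series(
        rng_threat.lognormal(0.0, 0.5, size=len(ecoregions)), index=ecoregions
    )
    if config.transboundary_threat_boost != 1.0:
        for eco in ecoregions:
            if len(membership[eco]) > 1:
                latent[eco] *= config.transboundary_threat_boost
    latent_unstoppable = pd.Series(
        rng_threat.lognormal(0.0, 0.5, size=len(ecoregions)), index=ecoregions
    )

    layer_mult = rng_threat.lognormal(0.0, 0.3, size=config.n_threat_layers)
    cell_latent_s = latent.loc[grid["ecoregion_id"]].to_numpy()
    cell_latent_u = latent_unstoppable.loc[grid["ecoregion_id"]].to_numpy()
    n_cells = len(grid)
    for i, lrow in layer_meta.iterrows():
        stoppable_truth = i < config.n_stoppable_layers
        lat = cell_latent_s if stoppable_truth else cell_latent_u
        for period, (shape, scale) in config.threat_distribution_params.items():
            vals = rng_threat.gamma(shape, scale * layer_mult[i] * lat, size=n_cells)
            grid[f"{lrow['layer_id']}_{period}"] = vals

    z = (latent - latent.mean()) / latent.std(ddof=0)
    mpas, allocations = _place_mpas(config, zones, z, rng_mpa)
    mpas = corrupt_years(
        mpas, config.missing_year_fraction,
        seed=int(rng_mpa.integers(2**31 - 1)),
    )

    truth = {
        "config": config.to_dict(),
        "latent_threat": {e: float(latent[e]) for e in ecoregions},
        "placement_score": {e: float(z[e]) for e in ecoregions},
    }
    return SyntheticWorld(grid=grid, layer_meta=layer_meta, zones=zones,
                          mpas=mpas, allocations=allocations, truth=truth)


def _place_mpas(config: WorldConfig, zones: pd.DataFrame, z: pd.Series,
                rng: np.random.Generator):
    """Place the estate wave by wave with softmax(beta*z) ecoregion draws."""
    ecoregions = list(z.index)
    eco_index = {e: i for i, e in enumerate(ecoregions)}
    weights = np.exp(config.bias_beta * z.to_numpy())
    weights /= weights.sum()

    zone_rem = zones["area_km2"].to_numpy().copy()
    zone_eco = zones["ecoregion_id"].to_numpy()
    zones_of_eco = {e: np.flatnonzero(zone_eco == e) for e in ecoregions}
    eco_rem = np.array([zone_rem[zones_of_eco[e]].sum() for e in ecoregions])

    total_area = float(zone_rem.sum())
    periods = sorted(config.total_protected_fraction_by_period)
    budgets, prev = [], 0.0
    for p in periods:
        frac = config.total_protected_fraction_by_period[p]
        if frac > 1.0:
            raise ValueError(f"infeasible protection fraction for period {p}")
        if frac < prev:
            raise ValueError(f"protection fraction decreases at period {p}")
        budgets.append((p, (frac - prev) * total_area))
        prev = frac
    median_size = (config.mpa_median_size
                   if config.mpa_median_size is not None
                   else prev * total_area / 100.0)
    if median_size <= 0:
        median_size = 1.0

    year_windows = {}
    lo = 1980
    for p in periods:
        year_windows[p] = (lo, p)
        lo = p + 1

    mpa_rows, alloc_rows = [], []
    counter = 0
    for period, budget in budgets:
        remaining = budget
        ylo, yhi = year_windows[period]
        while remaining > 1e-9 * total_area:
            size = float(rng.lognormal(math.log(median_size), config.mpa_size_sigma))
            size = min(size, remaining)
            # redraw saturated ecoregions (draw consumes nothing), as in the null
            for _ in range(10_000):
                ei = rng.choice(len(ecoregions), p=weights)
                if eco_rem[ei] > 1e-9:
                    break
            else:
                raise RuntimeError("all ecoregions saturated with budget remaining")
            alloc = min(size, eco_rem[ei])
            eco = ecoregions[ei]
            zi = zones_of_eco[eco]
            shares = zone_rem[zi] / zone_rem[zi].sum() * alloc
            zone_rem[zi] -= shares
            eco_rem[ei] -= alloc
            remaining -= alloc

            mpa_id = f"M{counter:04d}"
            counter += 1
            main = zi[int(np.argmax(shares))]
            mpa_rows.append({
                "mpa_id": mpa_id,
                "country_id": zones["country_id"].iat[main],
                "total_area_km2": float(alloc),
                "iucn_category": str(rng.choice(_IUCN_CATEGORIES, p=_IUCN_WEIGHTS)),
                "status": "designated",
                "is_unesco_biosphere": False,
                "has_boundary": True,
                "is_marine": True,
                "establishment_year": int(rng.integers(ylo, yhi + 1)),
            })
            for j, share in zip(zi, shares):
                if share > 0:
                    alloc_rows.append({
                        "mpa_id": mpa_id,
                        "country_id": zones["country_id"].iat[int(j)],
                        "ecoregion_id": eco,
                        "area_km2": float(share),
                    })

    # decoy records exercising the downstream filters; excluded from budgets
    n_decoys = max(2, round(0.06 * counter))
    fail_modes = ["proposed", "unesco", "no_boundary", "terrestrial"]
    for d in range(n_decoys):
        mode = fail_modes[d % len(fail_modes)]
        zrow = zones.iloc[int(rng.integers(len(zones)))]
        size = float(min(rng.lognormal(math.log(median_size), config.mpa_size_sigma),
                         zrow["area_km2"]))
        mpa_id = f"M{counter:04d}"
        counter += 1
        mpa_rows.append({
            "mpa_id": mpa_id,
            "country_id": zrow["country_id"],
            "total_area_km2": size,
            "iucn_category": str(rng.choice(_IUCN_CATEGORIES, p=_IUCN_WEIGHTS)),
            "status": "proposed" if mode == "proposed" else "designated",
            "is_unesco_biosphere": mode == "unesco",
            "has_boundary": mode != "no_boundary",
            "is_marine": mode != "terrestrial",
            "establishment_year": int(rng.integers(1980, max(periods) + 1)),
        })
        alloc_rows.append({
            "mpa_id": mpa_id,
            "country_id": zrow["country_id"],
            "ecoregion_id": zrow["ecoregion_id"],
            "area_km2": size,
        })

    mpas = pd.DataFrame(mpa_rows)
    mpas["establishment_year"] = mpas["establishment_year"].astype("Int64")
    allocations = pd.DataFrame(alloc_rows)
    return mpas, allocations


def corrupt_years(mpas: pd.DataFrame, missing_year_fraction: float,
                  seed: int) -> pd.DataFrame:
    """Blank the establishment year of exactly round(fraction*n) records.

    Deterministic for a fixed seed; a fraction of 0 returns an identical
    copy, a fraction of 1 blanks every record.
    """
    if not 0.0 <= missing_year_fraction <= 1.0:
        raise ValueError("missing_year_fraction must be in [0, 1]")
    out = mpas.copy()
    out["establishment_year"] = out["establishment_year"].astype("Int64")
    n_missing = int(round(missing_year_fraction * len(out)))
    if n_missing == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(out), size=n_missing, replace=False)
    out.iloc[idx, out.columns.get_loc("establishment_year")] = pd.NA
    return out


# ---------------------------------------------------------------------------
# on-disk representation (CSV tables + YAML truth); see docs/schema.md

_TABLES = ("grid", "layer_meta", "zones", "mpas", "allocations")


def write_world(world: SyntheticWorld, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(world, name).to_csv(directory / f"{name}.csv", index=False)
    with open(directory / "truth.yaml", "w") as fh:
        yaml.safe_dump(world.truth, fh, sort_keys=True)
    return directory


def read_world(directory: str | Path) -> SyntheticWorld:
    directory = Path(directory)
    tables = {}
    for name in _TABLES:
        tables[name] = pd.read_csv(directory / f"{name}.csv")
    for col in ("measured_2008", "measured_2013"):
        tables["layer_meta"][col] = tables["layer_meta"][col].astype(bool)
    mpas = tables["mpas"]
    for col in ("is_unesco_biosphere", "has_boundary", "is_marine"):
        mpas[col] = mpas[col].astype(bool)
    mpas["establishment_year"] = mpas["establishment_year"].astype("Int64")
    truth_path = directory / "truth.yaml"
    truth = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = yaml.safe_load(fh) or {}
    return SyntheticWorld(truth=truth, **tables)
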