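"""MPA filtering, establishment-year imputation and protection summaries.

Record filtering follows protected-area database conventions: terrestrial
records, proposed (not yet designated) sites, UNESCO Biosphere reserves and
records without delineated boundaries are excluded. Missing establishment
years are imputed by resampling, with replacement, from same-country records
with a known year (falling back to the global pool for countries with fewer
than five dated records); the mean of 1,000 draws is assigned. Protection is
then accumulated per (country, ecoregion) zone and per global ecoregion for
each period and each nested IUCN management-category grouping.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IUCN_GROUPINGS",
    "filter_mpas",
    "impute_years",
    "protection_by_zone",
    "protection_by_ecoregion",
    "protection_change",
]

_I_II = frozenset({"Ia", "Ib", "II"})
_I_IV = _I_II | {"III", "IV"}
_I_VI = _I_IV | {"V", "VI"}
_ALL = _I_VI | {"not_applicable", "not_reported", "not_assigned"}

#: nested IUCN groupings: strict reserves (I-II) ⊂ biodiversity-designated
#: (I-IV) ⊂ sustainable-use (I-VI) ⊂ all records incl. unclassified
IUCN_GROUPINGS: dict[str, frozenset[str]] = {
    "I-II": _I_II,
    "I-IV": _I_IV,
    "I-VI": _I_VI,
    "all": _ALL,
}


def filter_mpas(mpas: pd.DataFrame) -> pd.DataFrame:
    """Keep marine, designated, non-Biosphere records with boundary data."""
    keep = (
        mpas["is_marine"].astype(bool)
        & (mpas["status"] == "designated")
        & ~mpas["is_unesco_biosphere"].astype(bool)
        & mpas["has_boundary"].astype(bool)
    )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_mpas: removed %d of %d records", n_dropped, len(mpas))
    return mpas[keep].reset_index(drop=True)


def impute_years(mpas: pd.DataFrame, n_reps: int = 1000, seed: int | None = None,
                 per_country: bool = True, min_country_pool: int = 5) -> pd.DataFrame:
    """Fill missing establishment years by resampling known years.

    For each record with a missing year, `n_reps` years are drawn with
    replacement from the donor pool — same-country records with a known
    year if that pool has at least `min_country_pool` members, otherwise
    all records with a known year — and the mean of the draws, rounded to
    the nearest integer year, is assigned. With ``per_country=True``
    (default) one shared imputed year is computed per country and assigned
    to all of its missing records; with ``per_country=False`` each record
    gets an independent draw sequence.
    """
    out = mpas.copy()
    out["establishment_year"] = out["establishment_year"].astype("Int64")
    missing = out["establishment_year"].isna()
    if not missing.any():
        return out
    known = out.loc[~missing, ["country_id", "establishment_year"]]
    if known.empty:
        raise ValueError("cannot impute: no record has a known establishment year")
    global_pool = known["establishment_year"].astype(int).to_numpy()
    pools = {c: g["establishment_year"].astype(int).to_numpy()
             for c, g in known.groupby("country_id")}
    rng = np.random.default_rng(seed)

    def _draw(pool: np.ndarray) -> int:
        return int(round(rng.choice(pool, size=n_reps, replace=True).mean()))

    col = out.columns.get_loc("establishment_year")
    if per_country:
        for country in sorted(out.loc[missing, "country_id"].unique()):
            pool = pools.get(country, np.empty(0, dtype=int))
            if len(pool) < min_country_pool:
                pool = global_pool
            year = _draw(pool)
            rows = missing & (out["country_id"] == country)
            out.iloc[np.flatnonzero(rows), col] = year
    else:
        for i in np.flatnonzero(missing.to_numpy()):
            country = out["country_id"].iat[i]
            pool = pools.get(country, np.empty(0, dtype=int))
            if len(pool) < min_country_pool:
                pool = global_pool
            out.iloc[i, col] = _draw(pool)
    return out


def _qualifying(mpas: pd.DataFrame, period: int, grouping: str) -> pd.Series:
    if grouping not in IUCN_GROUPINGS:
        raise KeyError(f"unknown IUCN grouping {grouping!r}")
    if mpas["establishment_year"].isna().any():
        raise ValueError("establishment years must be imputed before summarising")
    return (mpas["establishment_year"].astype(int) <= period) & mpas[
        "iucn_category"
    ].isin(IUCN_GROUPINGS[grouping])


def protection_by_zone(mpas: pd.DataFrame, allocations: pd.DataFrame,
                       zones: pd.DataFrame, period: int,
                       grouping: str = "all") -> pd.DataFrame:
    """Protected area and proportion protected per (country, ecoregion) zone.

    A record contributes its zone allocations to a period iff its
    establishment year is at or before that period and its IUCN category
    belongs to the grouping. Proportions are clipped at 1 (overlapping
    designations can nominally exceed a zone's area); clipping is logged.
    """
    qual = mpas.loc[_qualifying(mpas, period, grouping), "mpa_id"]
    alloc = allocations[allocations["mpa_id"].isin(qual)]
    unknown = alloc.merge(zones[["country_id", "ecoregion_id"]],
                          on=["country_id", "ecoregion_id"], how="left", indicator=True)
    bad = unknown[unknown["_merge"] == "left_only"]
    if len(bad):
        pairs = sorted(set(zip(bad["country_id"], bad["ecoregion_id"])))
        raise ValueError(f"allocations reference unknown zones: {pairs}")

    prot = alloc.groupby(["country_id", "ecoregion_id"], as_index=False)[
        "area_km2"
    ].sum().rename(columns={"area_km2": "protected_area_km2"})
    out = zones.rename(columns={"area_km2": "zone_area_km2"}).merge(
        prot, on=["country_id", "ecoregion_id"], how="left"
    )
    out["protected_area_km2"] = out["protected_area_km2"].fillna(0.0)
    raw = out["protected_area_km2"] / out["zone_area_km2"]
    over = raw > 1.0 + 1e-12
    if over.any():
        for _, row in out[over].iterrows():
            logger.warning(
                "zone (%s, %s): protected %.1f km2 exceeds zone area %.1f km2; "
                "proportion clipped to 1",
                row["country_id"], row["ecoregion_id"],
                row["protected_area_km2"], row["zone_area_km2"],
            )
    out["proportion_protected"] = raw.clip(upper=1.0)
    out["period"] = period
    out["iucn_grouping"] = grouping
    return out[["country_id", "ecoregion_id", "period", "iucn_grouping",
                "protected_area_km2", "zone_area_km2", "proportion_protected"]]


def protection_by_ecoregion(mpas: pd.DataFrame, allocations: pd.DataFrame,
                            zones: pd.DataFrame, period: int,
                            grouping: str = "all") -> pd.DataFrame:
    """Global-ecoregion summary: pools each ecoregion's zones across countries."""
    z = protection_by_zone(mpas, allocations, zones, period, grouping)
    g = z.groupby("ecoregion_id", as_index=False).agg(
        protected_area_km2=("protected_area_km2", "sum"),
        zone_area_km2=("zone_area_km2", "sum"),
    )
    g["proportion_protected"] = (
        g["protected_area_km2"] / g["zone_area_km2"]
    ).clip(upper=1.0)
    g["period"] = period
    g["iucn_grouping"] = grouping
    return g[["ecoregion_id", "period", "iucn_grouping",
              "protected_area_km2", "zone_area_km2", "proportion_protected"]]


def protection_change(summary_2008: pd.DataFrame,
                      summary_2013: pd.DataFrame) -> pd.DataFrame:
    """Change in protection between the periods (2013 minus 2008) per unit."""
    keys = [c for c in ("country_id", "ecoregion_id") if c in summary_2008.columns]
    a = summary_2008.set_index(keys)
    b = summary_2013.set_index(keys)
    out = b[["zone_area_km2"]].copy()
    out["protected_area_km2"] = b["protected_area_km2"] - a["protected_area_km2"]
    out["proportion_protected"] = (
        b["proportion_protected"] - a["proportion_protected"]
    )
    out["iucn_grouping"] = b["iucn_grouping"]
    out["period"] = "2008-2013"
    return out.reset_index()
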