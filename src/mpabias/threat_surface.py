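"""Stoppable-threat classification, cross-period normalization, zonal means.

A threat layer is *stoppable* when an effectively managed MPA alone can abate
it (fishing pressures, benthic structures, direct human impacts); threats
originating on land or from diffuse sources (climate, land-based inputs) are
unstoppable. Layer values are min-max normalized per layer with the minimum
and maximum pooled over both measurement periods, so change between 2008 and
2013 is preserved on a common [0, 1] scale, and the mean stoppable threat of
each (country, ecoregion) zone is the area-weighted mean over its cells of
the per-cell mean across stoppable layers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "STOPPABLE_CATEGORIES",
    "VALID_CATEGORIES",
    "classify_stoppable",
    "make_rule_table",
    "analysis_layers",
    "normalize_across_periods",
    "mean_stoppable_threat",
    "ecoregion_mean_stoppable_threat",
]

STOPPABLE_CATEGORIES = frozenset({"fishing_pressure", "benthic_structure", "direct_human"})
VALID_CATEGORIES = frozenset(
    {"fishing_pressure", "benthic_structure", "direct_human",
     "climate", "land_based", "shipping", "other"}
)


def classify_stoppable(layer_meta: pd.DataFrame,
                       rule_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign a ``stoppable`` flag to each threat layer.

    By default a layer is stoppable iff its category is fishing pressure,
    benthic structure or direct human impact. `rule_table` — a frame with
    columns ``layer_id, stoppable`` — overrides individual layers, which
    supports sensitivity analyses such as treating only fishing pressure
    as abatable.
    """
    unknown = set(layer_meta["category"]) - VALID_CATEGORIES
    if unknown:
        raise ValueError(f"unknown threat categories: {sorted(unknown)}")
    out = layer_meta.copy()
    out["stoppable"] = out["category"].isin(STOPPABLE_CATEGORIES)
    if rule_table is not None:
        overrides = rule_table.set_index("layer_id")["stoppable"].astype(bool)
        missing = overrides.index.difference(out["layer_id"])
        if len(missing):
            raise ValueError(f"rule table names unknown layers: {list(missing)}")
        mask = out["layer_id"].isin(overrides.index)
        out.loc[mask, "stoppable"] = overrides.loc[
            out.loc[mask, "layer_id"]
        ].to_numpy()
    return out


def make_rule_table(layer_meta: pd.DataFrame,
                    stoppable_categories=("fishing_pressure",)) -> pd.DataFrame:
    """Build an override rule table flagging only the given categories stoppable."""
    return pd.DataFrame({
        "layer_id": layer_meta["layer_id"],
        "stoppable": layer_meta["category"].isin(set(stoppable_categories)),
    })


def analysis_layers(layer_meta: pd.DataFrame) -> pd.DataFrame:
    """Layers usable in the analysis: measured in both periods.

    Layers missing either period (e.g. shipping, measured once only) are
    dropped with a log message.
    """
    ok = layer_meta["measured_2008"].astype(bool) & layer_meta["measured_2013"].astype(bool)
    if not ok.all():
        dropped = layer_meta.loc[~ok, "layer_id"].tolist()
        logger.info("excluding layers not measured in both periods: %s", dropped)
    return layer_meta[ok].reset_index(drop=True)


def normalize_across_periods(grid: pd.DataFrame, layer_meta: pd.DataFrame,
                             periods=(2008, 2013)) -> pd.DataFrame:
    """Min-max rescale each layer using extremes pooled over both periods.

    Every layer in `layer_meta` must be measured in both periods. A layer
    that is constant across all cells and periods maps to 0 everywhere.
    Negative inputs are rejected: threat intensities are nonnegative.
    """
    usable = analysis_layers(layer_meta)
    out = grid.copy()
    for layer_id in usable["layer_id"]:
        cols = [f"{layer_id}_{p}" for p in periods]
        for c in cols:
            if c not in grid.columns:
                raise KeyError(f"grid lacks column {c!r}")
        block = out[cols].to_numpy(dtype=float)
        if np.any(block < 0):
            raise ValueError(f"negative threat values in layer {layer_id!r}")
        lo, hi = block.min(), block.max()
        if hi > lo:
            out[cols] = (block - lo) / (hi - lo)
        else:
            out[cols] = 0.0
    return out


def _cell_scores(grid: pd.DataFrame, layer_meta: pd.DataFrame, period: int,
                 agg: str) -> np.ndarray:
    stoppable = analysis_layers(layer_meta)
    stoppable = stoppable[stoppable["stoppable"].astype(bool)]
    if stoppable.empty:
        raise ValueError("no stoppable layers to aggregate")
    cols = [f"{lid}_{period}" for lid in stoppable["layer_id"]]
    vals = grid[cols].to_numpy(dtype=float)
    if agg == "mean":
        return vals.mean(axis=1)
    if agg == "sum":
        return vals.sum(axis=1)
    raise ValueError(f"unknown aggregation {agg!r}")


def mean_stoppable_threat(grid: pd.DataFrame, layer_meta: pd.DataFrame,
                          zones: pd.DataFrame, period: int,
                          agg: str = "mean") -> pd.DataFrame:
    """Area-weighted mean stoppable threat per (country, ecoregion) zone.

    Each cell's score is the mean (or, with ``agg='sum'``, the sum) of its
    normalized stoppable-layer values; the zonal statistic is the
    area-weighted mean of cell scores. Every zone must own at least one
    grid cell.

    Returns a frame with columns ``country_id, ecoregion_id, period,
    mean_stoppable_threat, n_cells``.
    """
    df = grid[["country_id", "ecoregion_id", "area_km2"]].copy()
    df["score"] = _cell_scores(grid, layer_meta, period, agg)
    df["wx"] = df["score"] * df["area_km2"]
    g = df.groupby(["country_id", "ecoregion_id"], as_index=False).agg(
        wx=("wx", "sum"), w=("area_km2", "sum"), n_cells=("score", "size")
    )
    merged = zones[["country_id", "ecoregion_id"]].merge(
        g, on=["country_id", "ecoregion_id"], how="left"
    )
    empty = merged[merged["n_cells"].isna()]
    if len(empty):
        missing = list(empty[["country_id", "ecoregion_id"]].itertuples(index=False, name=None))
        raise ValueError(f"zones with zero grid cells: {missing}")
    merged["mean_stoppable_threat"] = merged["wx"] / merged["w"]
    merged["period"] = period
    merged["n_cells"] = merged["n_cells"].astype(int)
    return merged[["country_id", "ecoregion_id", "period",
                   "mean_stoppable_threat", "n_cells"]]


def ecoregion_mean_stoppable_threat(grid: pd.DataFrame, layer_meta: pd.DataFrame,
                                    period: int, agg: str = "mean") -> pd.DataFrame:
    """Global-ecoregion aggregation: pools an ecoregion's cells across countries."""
    df = grid[["ecoregion_id", "area_km2"]].copy()
    df["score"] = _cell_scores(grid, layer_meta, period, agg)
    df["wx"] = df["score"] * df["area_km2"]
    g = df.groupby("ecoregion_id", as_index=False).agg(
        wx=("wx", "sum"), w=("area_km2", "sum"), n_cells=("score", "size")
    )
    g["mean_stoppable_threat"] = g["wx"] / g["w"]
    g["period"] = period
    return g[["ecoregion_id", "period", "mean_stoppable_threat", "n_cells"]]
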