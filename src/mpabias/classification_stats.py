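"""Sector classification, targeting/avoiding split, risk categories, chi-square tests.

Each ecoregion is binned by the quartiles of proportion protected and of mean
stoppable threat across all ecoregions into one of 16 sectors; if protection
were placed independently of threat, each sector would hold 6.25% of
ecoregions. The median threat splits ecoregions into a high- and a low-threat
class: protection in high-threat ecoregions *targets* stoppable threats,
protection in low-threat ecoregions *avoids* them. Ecoregions at or below the
median proportion protected are "poorly protected" and receive a risk
category by threat quartile — low risk, moderate risk, high risk, crisis.

Tie handling (surfaced here because many ecoregions share protection
exactly 0): quartile breakpoints are the 25/50/75th percentiles with linear
interpolation, values equal to a breakpoint fall in the lower bin, and the
high-threat / well-protected classes use strict ``>`` against the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ChiSquareResult",
    "quartile_assign",
    "quartile_sector_classify",
    "chi_square_uniform_sectors",
    "strategy_split",
    "risk_categories",
    "transboundary_test",
]

RISK_LABELS = {1: "low_risk", 2: "moderate_risk", 3: "high_risk", 4: "crisis"}


@dataclass
class ChiSquareResult:
    """A Pearson chi-square test against a stated expected table."""

    statistic: float
    df: int
    p_value: float
    observed: pd.Series | pd.DataFrame
    expected: pd.Series | pd.DataFrame
    extras: dict | None = None


def quartile_assign(values: pd.Series) -> pd.Series:
    """Quartile (1-4) per value; ties at a breakpoint fall in the lower bin."""
    v = values.to_numpy(dtype=float)
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    q = 1 + (v > q1).astype(int) + (v > q2).astype(int) + (v > q3).astype(int)
    return pd.Series(q, index=values.index)


def quartile_sector_classify(protection: pd.Series,
                             threat: pd.Series) -> pd.DataFrame:
    """Classify ecoregions into the 4x4 protection-by-threat sector grid.

    Parameters are per-ecoregion vectors on a common index: the proportion
    of area protected and the mean stoppable threat. Returns one row per
    ecoregion with ``protection_quartile``, ``threat_quartile``, the
    bijective ``sector`` number ``(protection_quartile-1)*4 +
    threat_quartile``, the median-split ``threat_class`` and
    ``poorly_protected`` flag, and the targeting/avoiding ``strategy``
    label implied by the threat class.
    """
    if not protection.index.equals(threat.index):
        threat = threat.reindex(protection.index)
        if threat.isna().any():
            raise ValueError("protection and threat must cover the same ecoregions")
    if len(protection) < 4:
        raise ValueError("need at least 4 ecoregions to form quartiles")

    pq = quartile_assign(protection)
    tq = quartile_assign(threat)
    threat_median = float(np.percentile(threat.to_numpy(dtype=float), 50))
    protection_median = float(np.percentile(protection.to_numpy(dtype=float), 50))
    high = threat > threat_median

    n_tied = int((protection == protection_median).sum())
    if n_tied > 1:
        logger.info(
            "quartile_sector_classify: %d ecoregions tied at the median "
            "protection value %.4g (ties fall in the lower bin)",
            n_tied, protection_median,
        )

    out = pd.DataFrame({
        "protection_quartile": pq,
        "threat_quartile": tq,
        "sector": (pq - 1) * 4 + tq,
        "threat_class": np.where(high, "high", "low"),
        "strategy": np.where(high, "targeting", "avoiding"),
        "poorly_protected": protection <= protection_median,
    })
    out.index.name = protection.index.name or "ecoregion_id"
    return out


def chi_square_uniform_sectors(classification: pd.DataFrame) -> ChiSquareResult:
    """Goodness of fit of sector counts against the uniform 1/16 expectation."""
    n = len(classification)
    if n == 0:
        raise ValueError("empty classification")
    observed = (
        classification["sector"].value_counts().reindex(range(1, 17), fill_value=0)
    ).sort_index()
    expected = pd.Series(n / 16.0, index=observed.index)
    if (expected < 5).any():
        logger.warning(
            "chi-square: expected count per sector %.2f < 5; "
            "asymptotic p-value may be unreliable", n / 16.0
        )
    statistic, p = stats.chisquare(observed.to_numpy(), expected.to_numpy())
    return ChiSquareResult(statistic=float(statistic), df=15, p_value=float(p),
                           observed=observed, expected=expected)


def strategy_split(protection: pd.DataFrame, threat_class: pd.Series) -> pd.DataFrame:
    """Protected area and proportions in the high- vs low-threat classes.

    `protection` is a per-ecoregion summary (columns ``protected_area_km2``
    and ``zone_area_km2`` indexed or keyed by ``ecoregion_id``);
    `threat_class` maps ecoregion to ``high``/``low``. Returns one row per
    class with the class's total and protected area, the area-weighted
    proportion protected, the unweighted mean of per-ecoregion proportions,
    and the share of all protection falling in that class (the ``high``
    row's share is the targeting share).
    """
    df = protection.copy()
    if "ecoregion_id" in df.columns:
        df = df.set_index("ecoregion_id")
    df["threat_class"] = threat_class.reindex(df.index)
    if df["threat_class"].isna().any():
        raise ValueError("threat_class missing for some ecoregions")
    df["prop"] = (df["protected_area_km2"] / df["zone_area_km2"]).clip(upper=1.0)
    g = df.groupby("threat_class").agg(
        protected_area_km2=("protected_area_km2", "sum"),
        class_area_km2=("zone_area_km2", "sum"),
        mean_ecoregion_proportion=("prop", "mean"),
        n_ecoregions=("prop", "size"),
    )
    g = g.reindex(["high", "low"]).fillna(
        {"protected_area_km2": 0.0, "class_area_km2": 0.0,
         "mean_ecoregion_proportion": 0.0, "n_ecoregions": 0}
    )
    g["proportion_protected"] = np.where(
        g["class_area_km2"] > 0,
        g["protected_area_km2"] / g["class_area_km2"], 0.0
    )
    total = g["protected_area_km2"].sum()
    g["share_of_protection"] = np.where(
        total > 0, g["protected_area_km2"] / total, np.nan
    )
    g["strategy"] = np.where(g.index == "high", "targeting", "avoiding")
    return g.reset_index()


def risk_categories(classification: pd.DataFrame) -> pd.DataFrame:
    """Risk category for poorly protected ecoregions, by threat quartile.

    Low risk (lowest quartile of stoppable threat), moderate risk (second),
    high risk (third), crisis (highest). Ecoregions above the median
    protection get no category.
    """
    out = classification.copy()
    cat = out["threat_quartile"].map(RISK_LABELS)
    out["risk_category"] = cat.where(out["poorly_protected"], other=pd.NA)
    return out


def transboundary_test(classification: pd.DataFrame,
                       n_countries: pd.Series) -> ChiSquareResult:
    """Are risk categories of poorly protected ecoregions border-dependent?

    `n_countries` maps each ecoregion to the number of countries whose EEZ
    it touches; more than one makes it transboundary. Within each border
    class the expected distribution is uniform: 25% of that class's poorly
    protected ecoregions in each of the four risk categories. A border
    class with no poorly protected ecoregions is skipped with a warning.
    The result's ``extras`` carries the share of all ecoregions that are
    transboundary.
    """
    if "risk_category" not in classification.columns:
        raise ValueError("run risk_categories first")
    border = np.where(
        n_countries.reindex(classification.index) > 1, "transboundary", "single_country"
    )
    cls = classification.assign(border_class=border)
    poor = cls[cls["poorly_protected"]]

    labels = [RISK_LABELS[i] for i in (1, 2, 3, 4)]
    obs_rows, exp_rows, used = [], [], []
    for bc in ("single_country", "transboundary"):
        sub = poor[poor["border_class"] == bc]
        if len(sub) == 0:
            logger.warning("transboundary_test: no poorly protected %s "
                           "ecoregions; class skipped", bc)
            continue
        counts = sub["risk_category"].value_counts().reindex(labels, fill_value=0)
        obs_rows.append(counts.rename(bc))
        exp_rows.append(pd.Series(len(sub) / 4.0, index=labels, name=bc))
        used.append(bc)
    if not used:
        raise ValueError("no poorly protected ecoregions in either border class")
    observed = pd.DataFrame(obs_rows)
    expected = pd.DataFrame(exp_rows)
    if (expected < 5).to_numpy().any():
        logger.warning("transboundary_test: some expected counts < 5")
    statistic = float((((observed - expected) ** 2) / expected).to_numpy().sum())
    df = 3 * len(used)
    p = float(stats.chi2.sf(statistic, df))
    share = float((n_countries > 1).mean())
    return ChiSquareResult(statistic=statistic, df=df, p_value=p,
                           observed=observed, expected=expected,
                           extras={"transboundary_share": share,
                                   "classes_tested": used})
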