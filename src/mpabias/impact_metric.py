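"""The impact metric, its random-allocation counterfactual null, and verdicts.

For a country C whose ecoregions are split at the median stoppable threat
into a high- and a low-threat class, the impact metric is

    I_C = p_H / a_H  -  p_L / a_L

with p the protected area and a the total area in each class. I_C is bounded
in [-1, 1]: -1 when only low-threat ecoregions are protected, +1 when only
high-threat ecoregions are protected, 0 when both classes are protected in
equal proportion. The null hypothesis is that countries protect area
randomly: ecoregions are drawn uniformly with replacement and each draw
allocates the country's median MPA size (capped so no ecoregion's proportion
protected exceeds 1) until the observed total protection is reached; I is
recomputed per simulation. An observed I outside the 95% confidence interval
of the mean simulated I differs significantly from random placement.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ImpactInputs",
    "NullResult",
    "impact",
    "random_allocation_null",
    "significance",
    "bias_ratios",
    "evaluate_impacts",
]

GLOBAL_ID = "GLOBAL"


@dataclass(frozen=True)
class ImpactInputs:
    """Areas feeding the impact metric, all in km²."""

    p_H: float
    p_L: float
    a_H: float
    a_L: float

    def __post_init__(self) -> None:
        if self.a_H < 0 or self.a_L < 0 or self.a_H + self.a_L <= 0:
            raise ValueError("class areas must be nonnegative with positive total")
        for p, a, name in ((self.p_H, self.a_H, "high"), (self.p_L, self.a_L, "low")):
            if p < 0 or p > a * (1 + 1e-9) + 1e-12:
                raise ValueError(
                    f"protected area exceeds class area in {name}-threat class"
                )

    @property
    def one_sided(self) -> bool:
        """True when the country has only one threat class."""
        return self.a_H == 0 or self.a_L == 0


def impact(inputs: ImpactInputs) -> float:
    """Evaluate I = p_H/a_H − p_L/a_L; a missing class contributes 0."""
    hi = inputs.p_H / inputs.a_H if inputs.a_H > 0 else 0.0
    lo = inputs.p_L / inputs.a_L if inputs.a_L > 0 else 0.0
    return hi - lo


@dataclass
class NullResult:
    """Outcome of the random-allocation simulations for one unit."""

    sims: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    ci_method: str
    mean_high_threat_protection: float
    allocations: np.ndarray | None = None


def _simulate(capacities: np.ndarray, high: np.ndarray, budget: float,
              median_pa_size: float, n_sims: int, rng: np.random.Generator,
              keep_allocations: bool = False):
    """Simulate random allocation.

    Returns (I per sim, high-class protection per sim, allocation matrix
    of shape (n_sims, n_ecoregions) or None).
    """
    n_eco = len(capacities)
    a_H = float(capacities[high].sum())
    a_L = float(capacities[~high].sum())
    caps = [float(c) for c in capacities]
    is_high = [bool(h) for h in high]
    sims = np.empty(n_sims)
    high_prot = np.empty(n_sims)
    alloc_mat = np.empty((n_sims, n_eco)) if keep_allocations else None
    # upper bound on draws per sim (including redraws of saturated ecoregions)
    block = max(16, int(budget / median_pa_size * 2) + 8)
    for s in range(n_sims):
        rem = caps.copy()
        remaining = budget
        p_H = 0.0
        draws = rng.integers(0, n_eco, size=block)
        pos = 0
        while remaining > 1e-9 * budget:
            if pos >= len(draws):
                draws = rng.integers(0, n_eco, size=block)
                pos = 0
            e = draws[pos]
            pos += 1
            r = rem[e]
            if r <= 1e-12:
                if max(rem) <= 1e-12:
                    raise RuntimeError("all ecoregions saturated with budget remaining")
                continue
            alloc = median_pa_size
            if r < alloc:
                alloc = r
            if remaining < alloc:
                alloc = remaining
            rem[e] = r - alloc
            remaining -= alloc
            if is_high[e]:
                p_H += alloc
        p_L = budget - p_H
        hi = p_H / a_H if a_H > 0 else 0.0
        lo = p_L / a_L if a_L > 0 else 0.0
        sims[s] = hi - lo
        high_prot[s] = p_H
        if keep_allocations:
            alloc_mat[s] = np.asarray(caps) - np.asarray(rem)
    return sims, high_prot, alloc_mat


def _confidence_interval(sims: np.ndarray, ci_mode: str,
                         rng: np.random.Generator) -> tuple[float, float, str]:
    """95% interval for the simulated metric, by the configured mode.

    ``mean-normal`` is the default: a normal-theory CI of the mean, with an
    automatic switch to a bootstrap percentile CI of the mean (1,000
    resamples) when a Shapiro-Wilk test rejects normality of the simulated
    values at alpha = 0.05. ``bootstrap`` forces the bootstrap CI.
    ``percentile`` instead takes the 2.5/97.5 percentiles of the simulated
    metric itself — an interval for a single random draw rather than for
    the mean, which is the appropriate yardstick for judging whether one
    observed estate looks like one random estate.
    """
    n = len(sims)
    mean = float(sims.mean())
    sd = float(sims.std(ddof=1)) if n > 1 else 0.0
    if ci_mode == "percentile":
        lo, hi = np.percentile(sims, [2.5, 97.5])
        return float(lo), float(hi), "percentile"
    if sd <= 1e-12 * max(1.0, abs(mean)):  # degenerate: all sims identical
        return mean, mean, "normal"
    method = ci_mode
    if ci_mode == "mean-normal":
        try:
            # Shapiro-Wilk is defined for n <= 5000; a 5000-subsample is ample
            p_norm = stats.shapiro(sims[:5000]).pvalue
        except ValueError:
            p_norm = 1.0
        method = "bootstrap" if p_norm < 0.05 else "normal"
    elif ci_mode == "bootstrap":
        method = "bootstrap"
    else:
        raise ValueError(f"unknown ci_mode {ci_mode!r}")
    if method == "normal":
        half = 1.96 * sd / math.sqrt(n)
        return mean - half, mean + half, "normal"
    means = rng.choice(sims, size=(1000, n), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi), "bootstrap"


def random_allocation_null(capacities: np.ndarray, high: np.ndarray,
                           budget: float, median_pa_size: float,
                           n_sims: int = 1000, seed: int | None = None,
                           ci_mode: str = "mean-normal",
                           keep_allocations: bool = False) -> NullResult:
    """Simulate random MPA allocation over one unit's ecoregions.

    Each simulation draws ecoregions uniformly with replacement and
    allocates ``median_pa_size`` (capped at the ecoregion's remaining
    capacity and the remaining budget) until the observed total protection
    ``budget`` is placed; draws landing on a saturated ecoregion consume
    nothing. The null impact metric is the mean of I over simulations.
    """
    capacities = np.asarray(capacities, dtype=float)
    high = np.asarray(high, dtype=bool)
    if median_pa_size <= 0:
        raise ValueError("median_pa_size must be positive")
    total = capacities.sum()
    if budget > total * (1 + 1e-9):
        raise ValueError(
            f"budget {budget:.6g} exceeds total ecoregion capacity {total:.6g}"
        )
    rng = np.random.default_rng(seed)
    if budget <= 0:
        sims = np.zeros(n_sims)
        high_prot = np.zeros(n_sims)
        alloc = np.zeros((n_sims, len(capacities))) if keep_allocations else None
    else:
        sims, high_prot, alloc = _simulate(
            capacities, high, float(budget), float(median_pa_size), n_sims,
            rng, keep_allocations=keep_allocations)
    lo, hi, method = _confidence_interval(sims, ci_mode, rng)
    return NullResult(sims=sims, mean=float(sims.mean()), ci_low=lo, ci_high=hi,
                      ci_method=method,
                      mean_high_threat_protection=float(high_prot.mean()),
                      allocations=alloc)


def significance(observed_I: float, null: NullResult) -> str:
    """Verdict against the null interval.

    ``better_than_random`` when the observed metric exceeds the interval
    (more protection targeting high-threat ecoregions than random
    placement yields), ``worse_than_random`` below it, else
    ``not_significant``.
    """
    if observed_I > null.ci_high:
        return "better_than_random"
    if observed_I < null.ci_low:
        return "worse_than_random"
    return "not_significant"


def bias_ratios(split: pd.DataFrame, observed_high_protection: float,
                random_high_protection: float) -> dict:
    """Headline disparity ratios.

    From a :func:`~mpabias.classification_stats.strategy_split` table and
    the observed/random high-threat protected areas, returns the low/high
    protection-proportion ratio, the random/observed high-threat
    protection ratio, and the percentage less protection observed in
    high-threat areas than random placement would have produced.
    """
    s = split.set_index("threat_class")
    prop_high = float(s.loc["high", "proportion_protected"])
    prop_low = float(s.loc["low", "proportion_protected"])
    if prop_high > 0:
        low_high = prop_low / prop_high
    else:
        logger.warning("bias_ratios: no observed high-threat protection; "
                       "low/high ratio is infinite")
        low_high = math.inf
    if observed_high_protection > 0:
        rand_obs = random_high_protection / observed_high_protection
        pct_less = 100.0 * (1.0 - observed_high_protection / random_high_protection) \
            if random_high_protection > 0 else math.nan
    else:
        logger.warning("bias_ratios: zero observed high-threat protection")
        rand_obs = math.inf
        pct_less = 100.0
    return {
        "low_high_protection_ratio": low_high,
        "random_observed_high_ratio": rand_obs,
        "percent_less_protection_high": pct_less,
        "targeting_share": float(s.loc["high", "share_of_protection"]),
    }


def _child_seed(seed: int | None, label: str) -> int:
    base = 0 if seed is None else int(seed)
    return (base * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def _split_classes(threat: pd.Series) -> pd.Series:
    """Median split: strict > is high threat, ties at the median are low."""
    med = float(np.percentile(threat.to_numpy(dtype=float), 50))
    return pd.Series(np.where(threat > med, "high", "low"), index=threat.index)


def evaluate_impacts(zone_protection: pd.DataFrame, zone_threat: pd.DataFrame,
                     eco_protection: pd.DataFrame, eco_threat: pd.DataFrame,
                     mpas: pd.DataFrame, n_sims: int = 1000,
                     seed: int | None = None, ci_mode: str = "mean-normal",
                     threat_split: str = "country",
                     min_ecoregions: int = 1,
                     include_global: bool = True,
                     include_countries: bool = True) -> pd.DataFrame:
    """Observed vs random impact metric per country and globally.

    Parameters
    ----------
    zone_protection, zone_threat : DataFrame
        Per-zone protection summary and mean stoppable threat for the
        evaluation period (keys ``country_id, ecoregion_id``).
    eco_protection, eco_threat : DataFrame
        The same quantities pooled per global ecoregion, used for the
        global estate.
    mpas : DataFrame
        Filtered records with imputed years; supplies the median MPA size
        per country (countries without records fall back to the global
        median).
    threat_split : {"country", "global"}
        Whether each country's high/low split uses the median over its own
        zones (default) or the median over all zones.
    min_ecoregions : int
        Skip countries with fewer zones than this.
    """
    if threat_split not in ("country", "global"):
        raise ValueError(f"unknown threat_split {threat_split!r}")
    zp = zone_protection.set_index(["country_id", "ecoregion_id"])
    zt = zone_threat.set_index(["country_id", "ecoregion_id"])["mean_stoppable_threat"]
    global_median = float(np.percentile(zt.to_numpy(), 50))
    sizes = mpas.groupby("country_id")["total_area_km2"].median()
    global_median_size = float(mpas["total_area_km2"].median())

    rows = []
    country_groups = zp.groupby(level="country_id") if include_countries else []
    for country, sub in country_groups:
        sub = sub.droplevel("country_id")
        if len(sub) < min_ecoregions:
            continue
        t = zt.loc[country]
        if threat_split == "country":
            classes = _split_classes(t)
        else:
            classes = pd.Series(np.where(t > global_median, "high", "low"),
                                index=t.index)
        rows.append(_evaluate_unit(
            country, sub, t, classes,
            float(sizes.get(country, global_median_size)),
            n_sims, _child_seed(seed, country), ci_mode,
        ))

    if include_global:
        ep = eco_protection.set_index("ecoregion_id")
        et = eco_threat.set_index("ecoregion_id")["mean_stoppable_threat"]
        classes = _split_classes(et)
        rows.append(_evaluate_unit(
            GLOBAL_ID, ep, et, classes, global_median_size,
            n_sims, _child_seed(seed, GLOBAL_ID), ci_mode,
        ))
    return pd.DataFrame(rows)


def _evaluate_unit(unit_id: str, protection: pd.DataFrame, threat: pd.Series,
                   classes: pd.Series, median_size: float, n_sims: int,
                   seed: int, ci_mode: str) -> dict:
    threat = threat.reindex(protection.index)
    classes = classes.reindex(protection.index)
    high = (classes == "high").to_numpy()
    areas = protection["zone_area_km2"].to_numpy(dtype=float)
    prot = np.minimum(protection["protected_area_km2"].to_numpy(dtype=float), areas)
    inputs = ImpactInputs(
        p_H=float(prot[high].sum()), p_L=float(prot[~high].sum()),
        a_H=float(areas[high].sum()), a_L=float(areas[~high].sum()),
    )
    observed = impact(inputs)
    budget = float(prot.sum())
    null = random_allocation_null(areas, high, budget, median_size,
                                  n_sims=n_sims, seed=seed, ci_mode=ci_mode)
    return {
        "country_id": unit_id,
        "n_ecoregions": len(protection),
        "observed_I": observed,
        "one_sided": inputs.one_sided,
        "random_mean_I": null.mean,
        "ci_low": null.ci_low,
        "ci_high": null.ci_high,
        "n_sims": n_sims,
        "ci_method": null.ci_method,
        "verdict": significance(observed, null),
        "observed_high_threat_protection": inputs.p_H,
        "random_high_threat_protection": null.mean_high_threat_protection,
    }
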