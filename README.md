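# mpabias

Quantifying placement bias of marine protected areas (MPAs) relative to
**stoppable threats** — the threats an effectively managed MPA can abate on
its own (fishing pressures, benthic structures, direct human impacts), as
opposed to climate or land-based pressures it cannot.

The package is aimed at conservation scientists and analysts who want to ask,
for a country's (or the world's) MPA estate: *is protection going where the
abatable threats are, or where they are not?* It provides:

- a tabular analysis pipeline over grid cells → (country, ecoregion) zones:
  stoppable-threat classification, cross-period min-max normalization, and
  area-weighted zonal threat means;
- protected-area accounting: database-style record filtering, Monte-Carlo
  imputation of missing establishment years, nested IUCN category groupings
  (I–II ⊂ I–IV ⊂ I–VI ⊂ all), and protection per zone and period;
- the 16-sector quartile classification of ecoregions by protection ×
  threat, risk categories for poorly protected ecoregions (low / moderate /
  high risk / crisis), and the associated chi-square tests, including the
  transboundary comparison;
- the **impact metric** with a **random-allocation counterfactual null**;
- a synthetic-world generator with a tunable placement bias, so every stage
  is testable against known ground truth without any external data.

## The impact metric

Split a country's ecoregions at the median stoppable threat into a
high-threat and a low-threat class, with class areas `a_H`, `a_L` and
protected areas `p_H`, `p_L`. Then

```
I_C = p_H / a_H − p_L / a_L        ∈ [−1, 1]
```

is 0 when both classes are proportionally equally protected, +1 when only
high-threat ecoregions are protected (pure *targeting*), −1 when only
low-threat ecoregions are protected (pure *avoiding*). The null hypothesis
is that the country places its protection at random: ecoregions are drawn
uniformly with replacement, each draw allocating the country's median MPA
size (capped so no ecoregion exceeds full protection) until the observed
2013 total is placed, and `I` is recomputed per simulation. An observed
metric outside the null's 95% interval is significantly better or worse
than random placement. See `docs/methods.md` for the interval modes and
tie-handling rules, and `docs/schema.md` for the table formats.

## Worked example

Simulate a small world whose estate *avoids* threat (placement bias
β = −1.5) and run the full pipeline:

```python
from mpabias import WorldConfig
from mpabias.pipeline import RunConfig, run_pipeline

config = RunConfig(
    out_dir="demo",
    world=WorldConfig(n_countries=4, n_ecoregions=16,
                      grid_cells_per_ecoregion=4, n_threat_layers=6,
                      n_stoppable_layers=3, transboundary_fraction=0.25,
                      bias_beta=-1.5, missing_year_fraction=0.1, seed=42),
    n_sims=1000, seed=42, ci_mode="percentile",
)
res = run_pipeline(config)
print(res["impact"]["impacts"][["country_id", "observed_I", "random_mean_I",
                                "ci_low", "ci_high", "verdict"]].round(4))
print(res["report"]["bias_ratios"])
```

prints

```
country_id  observed_I  random_mean_I  ci_low  ci_high           verdict
       C00     -0.0644         0.2444  0.1285   0.3618 worse_than_random
       C01     -0.2892        -0.0875 -0.1871   0.0100 worse_than_random
       C02     -0.0278        -0.0136 -0.0772   0.0486   not_significant
       C03     -0.2662        -0.0283 -0.1099   0.0550 worse_than_random
    GLOBAL     -0.1310         0.0242 -0.0078   0.0568 worse_than_random

{'low_high_protection_ratio': 8.66, 'random_observed_high_ratio': 6.05,
 'percent_less_protection_high': 83.48, 'targeting_share': 0.08}
```

Reading this: the global estate's observed impact metric (−0.131) lies below
the null's 95% band, so the simulated estate protects high-threat ecoregions
significantly *less* than random placement would — as it should, given the
avoiding bias built into the world. Low-threat ecoregions ended up with 8.7×
the proportional protection of high-threat ones; random allocation would
have put 6.1× more area into high-threat ecoregions than the estate did
(equivalently, the estate gives high-threat areas 83% less protection than
random); only 8% of all protected area targets threat. The same run writes
the full artifact set (zonal threat tables, protection summaries, sector and
risk classifications, chi-square reports, per-country impact results,
provenance) into `demo/`.

The identical analysis is scriptable from the shell:

```
mpabias simulate --n-countries 4 --n-ecoregions 16 --bias-beta -1.5 \
    --seed 42 --out world/
mpabias all --input world/ --out run/ --iucn all --n-sims 1000 --seed 42
```

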