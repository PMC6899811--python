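# Methods

`mpabias` quantifies whether a marine-protected-area (MPA) estate
preferentially protects ecoregions carrying high levels of *stoppable*
threat — threats an effectively managed MPA can abate on its own (fishing
pressures, benthic structures, direct human impacts) — or instead avoids
them, and compares the observed estate against a counterfactual in which the
same amount of protection is placed at random.

## Units of analysis

The world is tabular: grid cells, each with an area and per-layer threat
values in two periods (2008 and 2013), nest inside (country, ecoregion)
*zones*; zones of the same ecoregion across countries pool into *global
ecoregions*. No polygon geometry is used anywhere — zone membership and
areas are inputs, which keeps the pipeline independent of GIS tooling.

## Threat surface

Each threat layer carries a category; by default `fishing_pressure`,
`benthic_structure` and `direct_human` are stoppable and all others
(climate, land-based, diffuse) are not. A rule table can override individual
layers, e.g. a fishing-only sensitivity run. Layers not measured in both
periods are excluded outright (in the global data, shipping is the layer
lost this way).

Layer values are min-max normalized per layer with the minimum and maximum
pooled over both periods, so between-period growth survives rescaling; a
constant layer maps to 0 rather than NaN. A cell's score is the unweighted
mean of its normalized stoppable-layer values (configurable to a sum), and a
zone's mean stoppable threat is the area-weighted mean of its cells' scores.
Area weighting matters only for grids with unequal cell areas; on an
equal-area grid it reduces to the plain mean.

## Protection accounting

Records that are terrestrial, merely proposed, UNESCO Biosphere reserves, or
lack delineated boundaries are removed. Missing establishment years are
imputed by drawing, with replacement, 1,000 years from the same country's
dated records — or from all dated records when the country has fewer than
five — and assigning the rounded mean; by default one shared value is
computed per country (a per-record mode exists). Rounding to a whole year is
our choice; the year is integral in the source data and the gate
`year <= period` only ever compares integers.

A record contributes its zone allocations to a period iff its year is at or
before that period and its IUCN category lies in the active grouping; the
groupings are nested: I–II (strict reserves) ⊂ I–IV ⊂ I–VI ⊂ all
(including `not_applicable` / `not_reported` / `not_assigned`). Overlapping
designations can push a zone's nominal protected area past its area; the
proportion is clipped at 1 and the uncapped value is kept in the emitted
table with a logged warning.

## Classification and tests

Across all ecoregions, the quartiles of proportion protected and of mean
stoppable threat define a 4×4 sector grid (16 sectors); under placement
independent of threat each sector would hold 1/16 of ecoregions, tested with
a Pearson goodness-of-fit chi-square (df = 15). The same construction is
applied to the 2008→2013 *change* in protection against 2008 threat.

Ties: breakpoints are the 25/50/75th percentiles (linear interpolation
between order statistics); values equal to a breakpoint fall in the lower
bin, and the median splits use strict `>` for the high-threat /
well-protected side. This matters because protection is exactly 0 in many
ecoregions: with ties-go-low, all-zero ecoregions are quartile 1 and count
as poorly protected, which is the intended reading. The tie count at the
median is logged.

Ecoregions above the median threat are *high-threat* (protection there
*targets* threats); at or below, *low-threat* (protection there *avoids*
threats). Ecoregions at or below the median protection are *poorly
protected* and receive a risk category by threat quartile: low risk,
moderate risk, high risk, crisis. For the transboundary question, poorly
protected ecoregions are split into single-country vs border-crossing
classes, each compared against a uniform 25%-per-risk-category expectation
(df = 3 per class tested; an empty class is skipped with a warning).
Expected counts below 5 are logged but the tests still run, matching a
default Pearson test without continuity correction.

The proportion protected per strategy class is reported both area-weighted
(total protected / total class area — the default) and as the unweighted
mean of per-ecoregion proportions, since the two differ when large
ecoregions dominate.

## Impact metric and the random-allocation null

For one country (or the globe), with p the protected area and a the total
area in the high-/low-threat class,

    I_C = p_H / a_H − p_L / a_L ∈ [−1, 1].

0 means proportionally equal protection; −1/+1 mean only the low-/only the
high-threat class is protected. By default each country's high/low split
uses the median over its own zones (a global-median mode exists); the global
estate uses global ecoregions.

The null allocates the observed 2013 protection total at random: draw an
ecoregion uniformly with replacement, allocate the country's **median** MPA
size (robust to the long right tail of estate sizes) capped at the
ecoregion's remaining capacity and the remaining budget — so no ecoregion's
proportion exceeds 1 — until the budget is spent; saturated draws consume
nothing and are redrawn (an error is raised if all ecoregions fill while
budget remains, which feasibility checks prevent). Countries without any
record fall back to the global median size. 1,000 simulations are run; the
null metric is their mean.

Three interval modes decide significance:

- `mean-normal` (default): mean ± 1.96·sd/√n, switching automatically to a
  bootstrap percentile CI of the mean (1,000 resamples) when a Shapiro–Wilk
  test rejects normality of the simulated metrics at α = 0.05.
- `bootstrap`: forced bootstrap CI of the mean.
- `percentile`: the 2.5/97.5 percentiles of the simulated metric itself.

The first two produce an interval for the *mean* of the null, which shrinks
as n_sims grows — with enough simulations almost any observed estate is
"significant". The `percentile` mode answers the different, often more
useful question "does this one estate look like one random estate?", and is
the mode under which the package's type-I calibration property is stated.
Verdicts are `better_than_random` above the interval, `worse_than_random`
below, `not_significant` inside.

Headline ratios derived from the split and the null: the low/high
protection-proportion ratio, the random/observed high-threat protection
ratio, and the percent less protection in high-threat areas than random
placement would give (100·(1 − observed/random)).

## Synthetic worlds

The generator emulates the structural features the analysis depends on and
nothing more:

- **Structure.** 232 ecoregions across 20 countries by default, 63.4% of
  them transboundary (2–3 countries), matching the global tallies; zone
  areas are log-normal (median 1,000 km², log-sd 1) so a few large
  ecoregions dominate, which exercises the null's capacity capping; each
  ecoregion holds a fixed number of cells whose areas jitter around equal
  shares.
- **Threat.** Each ecoregion has a latent log-normal stoppable-threat level;
  stoppable-layer cell values are gamma draws whose scale is the latent
  level times a per-layer multiplier, with period means growing 1.0 → 1.15
  so 2008→2013 change exists. Unstoppable layers use an independent latent,
  so they carry no signal about placement. An optional multiplier boosts
  the latent threat of transboundary ecoregions for border-effect tests.
- **Protection.** Cumulative protected fractions default to 0.043 (2008)
  and 0.090 (2013) — 9.0% of national waters protected by 2013, 4.7% of it
  added after 2008. MPAs are placed by drawing an ecoregion with probability
  ∝ exp(β·z), z the standardized latent threat, then filling that
  ecoregion's zones in proportion to remaining capacity; β = 0 reduces
  exactly to the null's uniform draw law, β > 0 targets threat, β < 0
  avoids it. Estates also include a few decoy records (proposed, Biosphere,
  boundary-less, terrestrial) that the filters must remove, and a
  configurable fraction of blanked establishment years.
- **MPA sizes** are log-normal with log-sd 0.10: strictly right-skewed
  (median below mean, so the null's median-vs-mean distinction is real) but
  deliberately narrow. The observed metric's variance under unbiased
  placement scales with E[s²]/(m·E[s]) relative to the fixed-median-size
  null; wide size distributions make a truly random estate lumpier than the
  null it is judged against and over-reject. At log-sd 0.10 the type-I rate
  of the percentile-mode verdict is ≈5–7%, i.e. the unbiased generator is
  calibrated against the null. Heavier tails remain available via
  `mpa_size_sigma` for robustness studies, at the cost of that calibration.

All randomness derives from the single world seed through spawned child
streams; the pipeline derives stage seeds by hashing (seed, stage name), so
stage-level reruns reproduce full-run slices.

What the generator does **not** emulate: spatial autocorrelation within
ecoregions beyond the shared latent level, correlated threat layers,
MPA records spanning multiple ecoregions (each generated MPA sits in one),
reporting artefacts (duplicate records, inconsistent areas), and any real
geography. Passing tests therefore demonstrate the statistical machinery —
not that the global data would reproduce any particular published number,
which requires the real threat, protected-area and ecoregion datasets.

## Problem sizes and numerical choices

Statistical properties are verified on compact worlds (20 ecoregions ×
4 cells, 6 layers, 5 countries) so hundreds of seeds with 1,000-simulation
nulls run in minutes; structural properties use 16–32 ecoregions; the
classification oracle uses 232 ecoregions to match the global count.
Budget exhaustion uses a relative tolerance of 1e-9; degenerate null
distributions (all simulations identical) collapse the CI to a point;
Shapiro–Wilk is evaluated on at most 5,000 simulations (its defined range).

## Known limitations

- The per-country imputation assigns one shared year per country (the
  source procedure's reading); per-record imputation is a flag away and
  differs slightly in downstream variance.
- Chi-square p-values are asymptotic; with 16 sectors and few ecoregions
  the expected counts fall below 5 and the p-values are then indicative
  only (a warning is logged).
- The transboundary test conditions on the observed poorly protected sets;
  it does not model selection into poor protection.
- `mean-normal` significance inherits the paper-style sensitivity to
  n_sims discussed above; use `percentile` when judging a single estate.
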