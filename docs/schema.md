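# On-disk table schemas

A world directory (written by `mpabias simulate` or
`mpabias.synthetic_world.write_world`, read by `read_world`) holds five CSV
tables and one YAML file. All areas are km²; periods are calendar years
(2008, 2013); threat values are nonnegative intensities (arbitrary units
before normalization, [0, 1] after).

## grid.csv
One row per grid cell.

| column | type | meaning |
|---|---|---|
| `cell_id` | str | unique cell identifier |
| `country_id` | str | country owning the cell's EEZ portion |
| `ecoregion_id` | str | marine ecoregion containing the cell |
| `area_km2` | float | cell area |
| `<layer_id>_<period>` | float | threat-layer value for that cell and period (one column per layer per period) |

A cell belongs to exactly one (country, ecoregion) zone.

## layer_meta.csv
One row per threat layer.

| column | type | meaning |
|---|---|---|
| `layer_id` | str | layer identifier matching the grid column prefix |
| `category` | str | one of `fishing_pressure`, `benthic_structure`, `direct_human`, `climate`, `land_based`, `shipping`, `other` |
| `measured_2008`, `measured_2013` | bool | whether the layer was measured in that period; only layers measured in both are analysed |

The `stoppable` flag is not stored here; it is derived by
`threat_surface.classify_stoppable` (optionally overridden by a two-column
rule table `layer_id, stoppable`).

## zones.csv
One row per (country, ecoregion) zone.

| column | type | meaning |
|---|---|---|
| `country_id`, `ecoregion_id` | str | zone key |
| `area_km2` | float | zone area (equals the sum of its cells' areas) |

An ecoregion appearing under more than one country is transboundary.

## mpas.csv
One row per protected-area record (including records that downstream
filtering removes).

| column | type | meaning |
|---|---|---|
| `mpa_id` | str | unique record identifier |
| `country_id` | str | country holding the largest share of the MPA |
| `total_area_km2` | float | total MPA area (equals the sum of its allocations) |
| `iucn_category` | str | `Ia`, `Ib`, `II`, `III`, `IV`, `V`, `VI`, `not_applicable`, `not_reported`, `not_assigned` |
| `status` | str | `designated` or `proposed` (proposed records are filtered out) |
| `is_unesco_biosphere` | bool | UNESCO Biosphere reserve flag (filtered out) |
| `has_boundary` | bool | delineated boundary available (records without are filtered out) |
| `is_marine` | bool | marine record (terrestrial records are filtered out) |
| `establishment_year` | nullable int | calendar year; blank = unknown, to be imputed |

## allocations.csv
One row per (MPA, zone) area allocation.

| column | type | meaning |
|---|---|---|
| `mpa_id` | str | record identifier |
| `country_id`, `ecoregion_id` | str | zone receiving the area |
| `area_km2` | float | area allocated to that zone |

## truth.yaml
The generating `WorldConfig` plus ground truth (`latent_threat` and the
standardized `placement_score` per ecoregion). Present only for simulated
worlds; analysis stages never read it.
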