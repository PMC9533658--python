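# potholeveg

Vegetation-based condition assessment for prairie pothole wetlands.

Depressional "pothole" wetlands of the northern Great Plains are assessed
by surveying their plant communities: plants respond predictably to
disturbance, so floristic composition serves as a surrogate for overall
ecological condition. This package implements that workflow end to end for
temporarily and seasonally ponded potholes embedded in native-prairie or
reseeded (former cropland) grasslands:

* **Site selection** — stratified, spatially balanced sampling from a point
  frame via generalized random tessellation stratified (GRTS) addressing,
  with ordered alternates for replacing unsampleable primaries.
* **Vegetation surveys** — a zoned quadrat data model (exterior low-prairie,
  wet-meadow, and, for seasonal wetlands, central shallow-marsh zones; 8/7/5
  one-square-metre quadrats; between-quadrat species recorded with zone
  attribution), with delimited-text round-tripping.
* **Condition scoring** — the nine-metric Index of Plant Community
  Integrity (IPCI), with published value ranges shipped as editable YAML.
* **Reporting** — unweighted category counts and percentages with
  mean ± SD of index totals, by grassland type and hydrologic class.
* **Synthetic data** — a generator emulating pothole plant communities
  along a disturbance gradient, so every stage is testable without field
  data.

## The index

A wetland's species list (presence/absence, quadrat and between-quadrat
records alike) yields nine metrics: native-perennial richness and genus
count, native grass/grass-like richness, the percentage of annual,
biennial and introduced species, native-perennial richness in the
wet-meadow zone, counts of species at coefficient-of-conservatism
thresholds (C ≥ 5 wetland-wide; C ≥ 4 in the wet meadow), the average
C-value ($\bar{C}$), and the Floristic Quality Index

$$\mathrm{FQI} = \bar{C}\,\sqrt{N_{\text{native}}}.$$

Each metric maps through class-specific value ranges to an ordinal score
in {0, 4, 7, 11}; the nine scores sum to a 0–99 total, categorized as
Very poor … Very good (seasonally ponded) or Poor / Fair / Good
(temporarily ponded). C-values are expert-assigned integers 0–10
expressing a native species' fidelity to undisturbed habitat; introduced
species carry none.

## Worked example

```python
from potholeveg.ipci import assess, compute_metrics
from potholeveg.survey import *
from potholeveg.traits import *

tt = TraitTable()
tt.add(SpeciesTrait("Andropogon gerardii", "Andropogon", Nativity.NATIVE,
                    Lifespan.PERENNIAL, GrowthForm.GRASS, 8))
tt.add(SpeciesTrait("Balsamorhiza sagittata", "Balsamorhiza", Nativity.NATIVE,
                    Lifespan.PERENNIAL, GrowthForm.FORB, 5))
tt.add(SpeciesTrait("Bromus inermis", "Bromus", Nativity.INTRODUCED,
                    Lifespan.PERENNIAL, GrowthForm.GRASS))
tt.add(SpeciesTrait("Dalea candida", "Dalea", Nativity.NATIVE,
                    Lifespan.ANNUAL, GrowthForm.FORB, 1))

site = WetlandSite("wl-01", HydroClass.SEASONALLY_PONDED, "native", 2020)
survey = WetlandSurvey(site, [
    Observation("Andropogon gerardii", Zone.WET_MEADOW, 9),
    Observation("Balsamorhiza sagittata", Zone.LOW_PRAIRIE, 1),
    Observation("Bromus inermis", Zone.LOW_PRAIRIE, 1),
    Observation("Dalea candida", Zone.WET_MEADOW, 10),
])

print(compute_metrics(survey, tt).as_dict())
r = assess(survey, tt)
print(r.scores, r.total, r.category)
```

prints

```
{'richness_native_perennial': 2, 'genera_native_perennial': 2,
 'native_grass_grasslike': 1, 'pct_annual_biennial_introduced': 50.0,
 'wetmeadow_native_perennial': 1, 'count_c_ge_5': 2,
 'wetmeadow_count_c_ge_4': 1, 'avg_c': 4.67, 'fqi': 8.08}
(0, 0, 0, 0, 0, 0, 0, 11, 0) 11 Very poor
```

Two of the four species are native perennials; half the list is
short-lived or introduced, so the composition metric scores 0; the mean
C-value of the three scored natives, (8+5+1)/3 = 4.67, clears the
seasonal top class and contributes the only non-zero score. The total of
11 lands in the lowest seasonal category.

## The synthetic case study

The `analysis/` scripts run the whole design on synthetic data:

```sh
python analysis/01_select_sites.py --seed 1      # frame, 250-site draw, 24 replacements
python analysis/02_simulate_surveys.py --seed 1  # species pool + 200 surveys
python analysis/03_assess_condition.py           # per-wetland IPCI
python analysis/04_summarize_condition.py        # unweighted summaries
```

Each writes its tables under `results/`. The same pipeline is available
programmatically via `potholeveg.study.run_study`, and a `potholeveg` CLI
exposes `select`, `simulate`, `assess` and `summarize` subcommands.

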