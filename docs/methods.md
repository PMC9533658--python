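# Methods

## The assessment model

The package assesses the ecological condition of small depressional
prairie wetlands from plant species lists. Condition is operationalized
as the Index of Plant Community Integrity: nine presence/absence
community metrics, each mapped through published, class-specific value
ranges to an ordinal score in {0, 4, 7, 11} and summed to a 0–99 total,
which is mapped to a condition category. The two hydrologic classes
differ throughout: temporarily ponded wetlands have two concentric
vegetation zones (exterior low prairie, central wet meadow) and three
condition categories (Poor 0–33, Fair 34–66, Good 67–99); seasonally
ponded wetlands add a central shallow-marsh zone and use five categories
(Very poor 0–19, Poor 20–39, Fair 40–59, Good 60–79, Very good 80–99).
Both category systems partition [0, 99] exactly, which the test suite
verifies by exhaustive scan.

Metric semantics, and the policies adopted where a convention had to be
fixed:

* Metrics count **species**, never abundance. The wetland-level species
  list is the union of quadrat and between-quadrat records; the two
  wet-meadow metrics use the zone-attributed union. Between-quadrat
  records carry a zone label in the schema, so they enter zone-restricted
  metrics; without that attribution those metrics would be undefined for
  between-quadrat finds.
* The short-lived/introduced percentage counts the **union** of annual,
  biennial and introduced species once per species, over a denominator of
  **all** species recorded at the wetland — including species missing
  from the trait table, which enter no numerator (dropping them silently
  would bias the percentage downward). Unknown species trigger a warning.
* Native species lacking a C-value count toward the richness metrics and
  the FQI's $N_{\text{native}}$, but are excluded from the average-C and
  C-threshold metrics (standard floristic-quality practice).
* FQI = (unrounded mean C) × √(number of native species, any lifespan);
  only the final product is rounded. Using the unrounded mean avoids
  double-rounding drift at the 23.00 top-class boundary.

### Rounding and range lookup

The published ranges are stated at fixed precision (integers for counts,
one decimal for the percentage, two decimals for average C and FQI),
leaving apparent gaps such as 35.0 | 35.1 and 22.99 | 23.00. Metric
values are therefore rounded **half away from zero** to the metric's
printed precision before lookup, after which the ranges tile each
metric's achievable domain exactly; lookup then compares integer units,
avoiding float-boundary artifacts. The rounding convention at boundaries
is this package's policy (the source tables do not state one). A
hand-encoded oracle and dense grid scans in the test suite confirm the
YAML encoding and this lookup agree everywhere.

### Degenerate input

A survey with no recorded species yields the all-zero metric vector, and
`assess` assigns the all-zero score vector directly. The special case
exists because a literal table lookup would award the top score to the
0.0% short-lived/introduced share of an empty community; a wetland with
no plants has no community to credit, and totals 0 (Very poor or Poor by
class).

## Scoring configuration

The metric ranges and category ranges ship as a versioned, human-readable
YAML file (`potholeveg/data/ipci_scoring.yaml`) mirroring the published
tables cell for cell. Adapting the index to another region or wetland
class — where these specific ranges would not apply — is an edit to that
file, not a code change. The loader validates that every metric has
exactly the score set {0, 4, 7, 11}.

## Survey layout

Quadrat counts are protocol constants: 8 in low prairie, 7 in wet meadow,
5 in shallow marsh (1 m² each), so 15 quadrats per temporary and 20 per
seasonal wetland for any geometry. Zones are modeled as concentric
circular bands — real potholes are irregular, but no metric uses
geometry, so the circles are a layout/visualization convenience. "Evenly
distributed" is implemented as equal angular spacing on the band's
mid-radius ring from a seeded random start angle; the central zone uses
an Archimedean spiral with quadrat centers at equal arc-length steps.
When open water occupies part of a seasonal wetland's central zone, the
five central quadrats are split between open-water and emergent
placements by largest-remainder rounding on the open-water fraction,
which conserves the count for every fraction.

## Site selection

Selection uses generalized random tessellation stratified (GRTS)
sampling over a point frame. Each point gets a base-4 address by
recursive quadrant subdivision of the bounding box, with the four
quadrant digits independently permuted in every cell by a counter-based
generator keyed on (seed, level, cell index) — reproducible and
independent of visit order. Default depth is 8 levels, deepened until
addresses are unique (ties broken by site id). Within each stratum the
frame is sorted by address, a systematic sample with a seeded random
start is taken along that order, and the selected sites are re-ordered by
reverse hierarchical ordering (base-4 digits of the sample position,
reversed) so that **every prefix** of the ordered sample remains
spatially balanced. The first `n_primary` sites are the designed sample;
the rest are ordered alternates, consumed in order when a primary is
replaced (replacement never crosses strata). Only equal-inclusion
selection is implemented: the analysis is unweighted category counting,
so unequal inclusion probabilities would have nothing to feed.

Spatial balance is verified statistically: over 100 seeded replicates on
1000-point frames, the variance of frame-point counts over the sample's
Voronoi cells (nearest-sample-point assignment) is roughly a third of
that of equal-size simple random samples.

## Synthetic communities

The generator emulates the degradation pattern the index is built to
detect. The regional pool defaults to 70 native perennials (C-values from
a shifted binomial on 1–10, mean 5), 15 short-lived natives (mean C 2),
and 25 introduced species of which 8 are invasive mimics (the
smooth-brome / Kentucky-bluegrass / reed-canarygrass / hybrid-cattail
role). Pool generation, names (synthetic but binomial-shaped), growth
forms and per-species zone affinities (Dirichlet, tilted toward the wet
meadow) are deterministic given the seed.

Per wetland, species occupancy is independent Bernoulli. Expected total
richness declines geometrically with disturbance d from 65 to 16 species
(seasonal; 48 to 14 temporary) — undisturbed richness chosen so an intact
seasonal community clears the upper metric classes, degraded richness
reflecting the species-poor, invader-dominated communities typical of
disturbed potholes. Relative inclusion weights shift with d: native
perennials decay as exp(−0.35·d·C)·(1−0.9d), so conservative (high-C)
species drop out first; short-lived natives and introduced species rise
linearly; invasive mimics rise fastest (0.5 + 1.5d). Weights carry
lognormal noise (σ = 0.25) per species per wetland. Included species are
placed in zones by affinity and emitted as quadrat records (occupied
quadrat count ~ 1 + binomial) or, with probability 0.12, as a
between-quadrat record.

At these defaults — fixed once, as the study conditions — seeded
replicates of seasonal wetlands assess Good/Very good at d = 0 and
Poor/Very poor at d = 1 in well over 80% of draws, and the mean total is
monotone decreasing across d ∈ {0, 0.25, 0.5, 0.75, 1} (Spearman ρ ≤
−0.9): the pipeline recovers the gradient it was given. The synthetic
case study (`potholeveg.study`) draws 250 sites from a 1000-point frame
stratified by class × year (50 primaries per stratum, 13/13/12/12
alternates), replaces 24 primaries, surveys the 200 active primaries
with 48 in native prairie, and gives reseeded sites a baseline
disturbance offset of +0.35 over a base level uniform on [0, 0.55] —
producing the qualitative native ≫ reseeded ordering without targeting
any particular percentage.

What the generator does **not** emulate: species co-occurrence structure
(occupancy is independent per species), abundance and cover dynamics,
hydrology, inter-annual climate variability, seed banks, or observer
error. Passing tests therefore demonstrate that the scoring machinery,
design algebra and reporting are correct and that the index responds to a
known richness/composition gradient — not that field communities behave
like the generator.

## Reporting

Summaries are deliberately unweighted: number and percent of wetlands per
condition category (percentages to one decimal, half-away-from-zero) and
mean ± SD of totals per group, with SD using the n−1 denominator. Being
category counts, the results carry no confidence intervals, and none are
computed.

## Problem sizes and determinism

Simulation-backed checks use 200 replicates per gradient point, 100
replicates for the spatial-balance comparison (1000-point frames, 50-site
samples), and a 200-wetland synthetic study — sizes at which every
statistical assertion is stable across seeds while the whole suite runs
in well under a minute of compute. Every random component (pool, surveys,
frames, draws, replacements) flows from explicit integer seeds through
`numpy` SeedSequence spawning, so identical seeds give byte-identical
outputs.
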