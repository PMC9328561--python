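# Methods

## The accessibility model

`fca-access` measures spatial accessibility to HIV services with the
enhanced two-step floating catchment area (E2SFCA) method. Supply is a set
of service sites `j`, each flagged for one or more service layers — testing,
treatment (Ryan White HIV/AIDS Program care), and prevention (PrEP) — with
capacity `S_j` (1 by default: availability, not throughput, is measured).
Demand is a set of population units `k` carrying counts `P_k` for three
populations: people living with HIV (PLWH, the demand group for treatment),
men who have sex with men (MSM, a demand group for testing and prevention),
and adults aged 15–64 (testing and prevention). Travel is either driving on
a road network with per-edge speeds or public transit over a stop graph at a
constant speed (10 mph by default).

**Step 1 (supply-to-population ratio).** Each site's catchment is built from
the network: nodes reachable within the zone breaks (10, 20, 30 minutes by
default) are found by Dijkstra's algorithm, and the convex hull of each
reachable node set forms the zone polygon. The hulls are nested by
construction; zone *r* is the ring between consecutive hulls. Population
unit centroids falling inside the outermost hull contribute to the site's
denominator:

    R_j = S_j / Σ_{k : centroid_k ∈ hull_3} P_k            ("as_printed")
    R_j = S_j / Σ_r Σ_{k ∈ ring_r} P_k · W_r               ("weighted")

with decay weights `W = (1, 0.68, 0.22)` for the 0–10, 10–20, and 20–30
minute zones. Both step-1 variants are implemented. `as_printed` leaves the
denominator unweighted; `weighted` is the standard E2SFCA form, for which
total delivered supply is conserved: with demand evaluated at unit
centroids, `Σ_k P_k A_k = Σ_j S_j` exactly (over sites with nonzero
catchment population). The default is `as_printed`; `weighted` is
recommended when the conservation property matters.

**Step 2 (accessibility).** At any location `i`,

    A_i = Σ_j R_j · W_{r(i,j)}

summing over sites whose catchment contains `i`, where `r(i,j)` is the zone
of `i` in site `j`'s catchment. Values are aggregated onto a flat-top
hexagon grid (hexagons reduce the orientation bias square grids show at
zone edges): each cell takes `A` at its representative point (the hexagon
center). Surfaces are min–max normalized to `[0, 1]`.

**Transit.** Travel time between two points is the shortest stop-graph path
between their nearest stops, divided by the constant transit speed. Access
and egress legs are excluded by default (stop-to-stop travel); a configurable
walk speed can add straight-line walk legs. Timetables, headways, waiting
and transfer penalties are out of scope.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| zone breaks | 10, 20, 30 | min | last break is the catchment threshold d0 |
| zone weights | 1, 0.68, 0.22 | — | must be non-increasing, in (0, 1] |
| site capacity S_j | 1 | sites | availability-only supply model |
| transit speed | 10 | mph | constant; timetables ignored |
| hexagon width | 500 (city) / 5000 (state) | m | width across flats, flat-top |
| step-1 variant | as_printed | — | "weighted" enables conservation |
| snap tolerance | 2 × median edge length | m | exceeded → logged warning, snap anyway |

Numerical choices: a degenerate hull (fewer than three non-collinear
reachable nodes) is buffered by ε = half the median edge length so every
site has a nonzero-area catchment; points on a shared ring boundary belong
to the inner ring; a site whose catchment holds zero population gets
`R_j = 0` (logged) rather than an infinity; a constant surface normalizes
to all zeros with a warning; nearest-node ties break to the smallest node
id; MSM estimates round half to even and clamp to `[0, male_pop]`.

## MSM estimation

MSM counts per unit are derived from same-sex-male (SSM) household data,
stratified by urbanicity:

    MSM_k = male_pop_k · p_base(urb_k) · (ssm_share_k / ssm_ref(urb_k))

in `proportional` mode; `baseline-only` mode drops the household rescaling.
The per-urbanicity constants (`p_base`, `ssm_ref`) ship as documented
placeholders of plausible magnitude (urban MSM share of adult males a few
percent, rural near one percent) and should be replaced with study-specific
values via the YAML parameter table; the formula structure is fixed, the
constants are not. Both the household-share and baseline-only variants are
supported because published small-area estimators differ in this choice.

Unit centroids are geometric (shapely) centroids; a population-weighted
centroid would need sub-unit population data the model does not assume.

## The synthetic-city generator

The generator replaces the external inputs a real study assembles (a road
network extract, a transit feed, a service-site registry, census population
layers) with seeded synthetic analogues:

- **Road network**: a connected planar grid with jittered node coordinates;
  per-edge speeds scalar or sampled from a range. The city preset is a
  24 × 24 grid at 1.2 km spacing (a ~28 km metro region) at 25 km/h, so
  30-minute catchments are genuinely partial — at smaller scales every
  catchment covers the whole region and the supply ratios degenerate to a
  common constant.
- **Transit overlay**: routes along alternating grid rows and columns with
  stops every ~1 km; crossing routes always share a transfer stop, keeping
  the stop graph connected.
- **Service sites**: rejection-sampled with exponential center attraction;
  flags drawn from a configurable service-mix distribution whose default
  anchors the fraction of sites offering all three services at ≈ 0.545
  (roughly 600 of 1,100 in a registry of realistic composition).
- **Population units**: square tiles; the 15–64 population follows a
  lognormal share model apportioned by largest-remainder rounding so unit
  sums equal the configured totals exactly; PLWH and MSM are multinomial
  with center-weighted probabilities (uniform when clustering is 0), capped
  per unit at the 15–64 count with deterministic redistribution of any
  overflow. City totals default to 1,000,000 adults 15–64, 20,000 PLWH,
  50,000 MSM.
- **`underserved_demo`**: the city scenario with a planted low-access
  region — the south-west quadrant receives no sites and a 3× demand boost,
  so it should (and, in the acceptance checks, does) come out with the
  strictly lowest quadrant-mean normalized accessibility.

Everything derives from one integer seed through per-stage RNG streams, so
a fixed seed gives byte-identical serialized outputs regardless of the
order stages run in.

What the generator does **not** emulate: real street topology, timetable
GTFS (calendars, headways, frequencies), demographic covariance between the
three populations, boundary effects with neighboring regions, or variable
site capacity. Passing tests therefore demonstrate correctness of the
method's mechanics and its qualitative behavior (decay, dominance,
disparity recovery) on data with the assumed statistical structure, not
fidelity to any particular real city.

## Statistics

Surface comparisons use nonparametric tests on hexagon-cell values of
normalized accessibility: Kruskal–Wallis (tie-corrected, chi-square
reference with k−1 df) across the five (service, population) surfaces per
mode; Dunn's pairwise z-tests on mean ranks with Bonferroni adjustment; and
Mann–Whitney U (exact enumeration when both n ≤ 8, otherwise tie-corrected
normal approximation with continuity correction) for the drive-vs-transit
contrast per surface, reporting which mode stochastically dominates. All
p-values are two-sided. Cells with A = 0 are real low-access observations
and are included. Fully tied inputs return H = 0 / p = 1 rather than an
error. Cell-wise means are reported with normal-approximation 95%
confidence intervals across cells.

Known caveat: hexagon cells are spatially autocorrelated, so the effective
sample size is smaller than the cell count and p-values are anti-
conservative. This is documented, not corrected.

## Problem sizes in tests and the acceptance script

Exact-agreement checks (brute-force oracle, conservation) run on 20 random
instances of ≤ 5 sites and ≤ 20 units on 5–7 node-per-side lattices; the
shortest-path enumeration oracle uses a 9-node graph where all simple paths
can be enumerated. Monotonicity uses 100 perturbations of a 6-site city
subset on a 1.5 km grid; mode dominance uses a compact 8 × 8 shared-geometry
scenario (where equal step-1 denominators make per-cell dominance a
theorem under the `as_printed` variant); underserved recovery runs the city
pipeline for 10 seeds; the Kruskal–Wallis null calibration uses 2,000
replicates of 4 × 50 observations. These sizes were chosen so every check
runs comfortably on a laptop while remaining statistically meaningful.

## Known limitations

- Node-based reachability: partial traversal of an edge beyond the last
  reachable node is ignored, and convex hulls can over-cover concave
  reachable sets (an alpha-shape option is a natural extension).
- The min–max normalization is a choice; other normalizations (e.g. by
  mean, or rank) would change reported magnitudes but not orderings.
- Transit routing is frequency- and timetable-free; multimodal chains
  (walk + bus + walk, drive + park) are out of scope.
- Cross-boundary demand and supply (people using services outside the
  study region) are not modeled, biasing edge accessibility downward.
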