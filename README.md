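# fca-access

Spatial accessibility to HIV testing, treatment, and prevention services,
measured with the enhanced two-step floating catchment area (E2SFCA)
method, for the three populations the CDC's service recommendations target:
people living with HIV (PLWH — treatment), men who have sex with men
(MSM — testing and PrEP prevention), and adults aged 15–64 (testing and
prevention). The package is aimed at health-geography and HIV-program
analysts who need reproducible access surfaces and disparity statistics
for a city or state, under either driving or public-transit travel.

## The method

Each service site *j* gets a supply-to-population ratio over its
network-travel-time catchment, delineated as convex hulls of road nodes
reachable within 10 / 20 / 30 minutes:

```
R_j = S_j / Σ_{k : d_kj ≤ d0} P_k
```

and accessibility at a location *i* sums the ratios of all reachable sites,
discounted by travel-zone distance-decay weights
W = (1, 0.68, 0.22):

```
A_i = Σ_j R_j · W_{r(i,j)}
```

Results are aggregated on flat-top hexagon grids (500 m city scale, 5 km
state scale), min–max normalized, and compared with Kruskal–Wallis, Dunn
(Bonferroni), and Mann–Whitney tests. Transit travel uses the stop graph of
a GTFS text subset at a constant 10 mph. A `weighted` step-1 variant
(decay weights in both steps, the standard E2SFCA form, which conserves
total delivered supply) is available alongside the default unweighted
denominator. Details, defaults, and numerical edge rules are in
[docs/methods.md](docs/methods.md).

Because real registries and census layers are usually license-encumbered,
the package ships a seeded synthetic-city generator (road grid, transit
overlay, center-clustered sites with a realistic service mix, heterogeneous
population tiles) plus an `underserved_demo` scenario that plants a
high-demand, zero-site quadrant the pipeline should flag.

## Worked example

```
$ fca-access run -c config.yaml        # or, equivalently, from Python:
```

```python
from fca_access.pipeline import RunConfig, run

out = run(RunConfig(output_dir="out", preset="city", seed=7,
                    modes=("drive", "transit")))
for s in out["report"]["summaries"][:2]:
    print(s["surface"], round(s["mean_normalized"], 4),
          [round(x, 4) for x in s["ci95"]])
```

prints

```
prevention:msm:drive 0.4577 [0.4514, 0.4639]
prevention:msm:transit 0.1313 [0.1261, 0.1366]
```

i.e. on this synthetic city (3,552 hexagon cells), mean normalized
accessibility of PrEP sites for MSM is 0.46 driving but 0.13 by transit —
transit users see far less of the service supply within 30 minutes. The
report also contains the across-surface heterogeneity test per mode
(`H = 425.05, p < 0.001` for driving here), Dunn pairwise contrasts, and
one Mann–Whitney drive-vs-transit test per surface (all with direction
`drive` on this scenario). `out/` holds one GeoJSON hexagon surface per
(service, population, mode) with `A` and `A_normalized` properties — ready
to drop into any GIS viewer — plus `report.json` and a provenance sidecar.

The stages are also separately runnable and compose to the same bytes:

```
fca-access synth --preset city --seed 7 -o inputs/
fca-access travel -i inputs/ -o zones/ --mode drive --mode transit
fca-access e2sfca -i inputs/ -z zones/ -o surfaces/ --mode drive --mode transit
fca-access stats surfaces/*.geojson -o report.json
```

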