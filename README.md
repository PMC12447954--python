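# paleoneuro

Quantitative paleoneurology from endocast measurement tables: encephalization
quotients, neocorticalization trends through geologic time, brain–body convex
polygons, surface–volume scaling, and within-species variation statistics.

## The problem

Cranial endocasts — natural, cast, or virtual molds of the braincase — are the
only direct record of brain evolution in deep time. Given a table of endocast
measurements (surface area S, olfactory-bulb area OB, neocortex area NC,
length L, endocranial volume E, body mass P, geologic age), a comparative
morphometrician wants to answer, reproducibly:

- **How encephalized is a specimen?** Brain size follows body mass as a power
  law, E = b·P^α. With the classical theoretical choices α = 2/3 and b = 0.12
  (cgs units: ml and g), the encephalization quotient
  **EQ = E / (0.12·P^(2/3))** is the observed brain size relative to
  expectation; EQ = 1 is exactly average.
- **How neocorticalized, and how has that changed?** The rhinal fissure is
  the one neocortex boundary visible on an endocast, so
  **%NC = 100·NC/(S − OB)**. Regressing %NC on geologic age measures the
  pace of neocortical expansion across the Cenozoic.
- **Where is the mammal–reptile boundary?** Classes occupy convex polygons in
  (log₁₀ P, log₁₀ E) space; a fossil classifies *inside*, *above*, or *below*
  a group's polygon, and the reptile polygon can be extended to dinosaur body
  sizes before asking whether an archaic mammal still clears it.
- **How does surface scale with volume?** OLS of log₁₀ S on log₁₀ E,
  compared against the geometric reference exponent 2/3, plus a per-specimen
  convolutedness index.
- **Is one specimen enough to represent a species?** Within-species
  coefficients of variation (sample SD / mean) over repeated endocasts of a
  single species.

Two verbatim published measurement tables ship as fixtures: a 158-row mammal
table (117 fossil specimens, 22 living non-primates, 19 living primates) and
an 8-specimen *Bathygenys reevesi* within-species table. A synthetic-data
generator reproduces the statistical structure these analyses assume
(power-law brain–body scaling with lognormal residuals, a monotone %NC trend
with saturation, lognormal within-species variation) so every estimator is
tested against known truth.

## Worked example

```python
>>> from paleoneuro import load_table, eq, trend_vs_time, variation_table
>>> table = load_table("table1_mammals")
>>> len(table)
158
>>> coyote = next(r for r in table if r.species == "Canis latrans")
>>> round(eq(coyote.E, coyote.P).eq, 2)   # 97.85 ml at 15,000 g
1.34
>>> fit = trend_vs_time(table, predict_at=(0.0, -60.0))
>>> round(fit.slope * 10, 1)              # %NC gained per 10 Myr
7.5
>>> [round(p, 1) for _, p in fit.predictions]
[59.2, 14.3]
```

The coyote endocast holds 1.34× the brain expected for its body mass; the
mammals in the table gained about 7.5 percentage points of neocortex per
10 Myr, from ~14% of endocast surface at 60 Ma to ~59% today.

The same stages are scripted end to end under `analysis/` (numbered drivers
that write tables to `results/`) and exposed on the command line:

```sh
paleoneuro validate  --input table1_mammals
paleoneuro eq        --input table1_mammals --out eq.csv
paleoneuro nc-trend  --input table1_mammals --predict-at 0,-60
paleoneuro polygons  --input table1_mammals --classify "Arctocyon:16144:7.14"
paleoneuro variation --input table2_bathygenys
paleoneuro scaling   --input table1_mammals
paleoneuro simulate  --seed 17 --out synthetic.csv
paleoneuro reproduce-paper --out-dir results
```

`paleoneuro reproduce-paper` re-runs every fixture-backed arithmetic check
(printed %NC and EQ cells, reproduction rates, the flagged *Equus
occidentalis* inconsistency, trend ranges, within-species CVs) and writes
`results/reproduce_paper.json`; it exits 0 only if all checks pass.

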