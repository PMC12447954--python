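# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `paleoneuro`. Everything quantitative stated here is
computed by the test suite or the `analysis/` drivers; nothing is asserted
that the code does not itself verify.

## Data model and units

A specimen is one endocast or brain: surface area S, olfactory-bulb area OB,
surface excluding bulbs S−OB, neocortex area NC (all cm²), endocast length L
(cm), geologic age (Ma, ≤ 0 with 0 = extant), endocranial volume E (ml ≡ g),
body mass P (g), plus the published %NC and EQ columns. All analyses assume
the cgs convention; the allometric intercept b is unit-dependent, so
quotients computed from kg or mm³ are meaningless, and the documentation of
`allometry.eq` says so explicitly.

Missing cells are `None`, never zero — with one deliberate exception:
OB = 0 is a real measurement meaning the olfactory bulbs were absent from
the cast, distinct from a blank cell. Downstream stages declare which fields
they need (`dataset.require_fields`) and drop only rows missing those
fields, logging the drop count; no stage ever silently discards a row.

The loader normalizes the handful of fossil rows printed with positive ages
(recent tar-pit material, plus one typo) to negative, logging each flip.
Duplicate specimens of one species are kept as separate rows; nothing is
averaged at load time.

### The packaged tables

`table1_mammals.csv` is a verbatim transcription of the published mammal
measurement table: 158 rows — 117 fossil, 22 living non-primate, 19 living
primate. The published fossil-section header says 118, but only 117 fossil
measurement rows exist in the published table text; the missing specimen
(*Neohipparion*, FMNH P 15871) appears in a figure and has no recoverable
measurements, so it is absent here rather than fabricated. Numeric cells are
byte-faithful to the publication, including cells that are internally
inconsistent (below). `table2_bathygenys.csv` is the 8-specimen
*Bathygenys reevesi* within-species table (volume, surface, neocortex area,
neocortex:surface ratio).

### Validation, not correction

`validate_records` recomputes every derivable column and reports
pass/fail/skipped per record; failures never raise and records are never
mutated or corrected. On the packaged table, 149/152 %NC cells reproduce
within 0.05 percentage points and 153/154 EQ cells within 0.01 after
2-decimal rounding. The exceptions are pinned by regression tests: the
*Equus occidentalis* %NC cell prints 85.19 where its own NC and S−OB give
58.66 (the one materially wrong cell — all trend analyses therefore prefer
recomputed %NC over the printed column), plus two sub-0.2-point rounding
slips and one EQ cell off by 0.18. The additivity check S ≈ OB + (S−OB)
fails for six rows, mostly casts whose bulbs were damaged or absent, where S
was measured on a different extent than S−OB; these are reported, not
"fixed".

## Reference allometry and EQ

EQ = E / (b·P^α) with α the exact double-precision fraction 2/3 (a decimal
truncation like 0.67 visibly shifts large-bodied quotients) and b = 0.12.
The intercept is not stated alongside the published table, but back-solving
b = E / (EQ·P^(2/3)) per row and taking the median over 154 complete rows
gives 0.1199 — the classical mammalian constant; `derive_b` performs this
inversion and a test pins it. Empirical slopes are available via OLS of
log₁₀ E on log₁₀ P (`fit_loglog`), with reduced-major-axis as an explicit
option, never the default: the analyses here follow bivariate regression
practice.

The body-length relation P = 0.021·L^3.03 is exposed
(`body_mass_from_length`) but never used to impute body masses: the table's
L column is endocast length, not body length, and the two must not be
conflated.

## Neocorticalization

%NC = 100·NC/(S−OB), olfactory bulbs excluded because they are unreliably
preserved. The trend through time is OLS of %NC on age over every row with
both quantities (n = 152): slope 0.748 %/Myr (≈ 7.5 points per 10 Myr),
predicting 59.2% at present and 14.3% at 60 Ma — within the 50–65% and
10–25% windows the published summaries bracket. Two flags alter the
population: `exclude_recent_Ma` drops sub-recent fossils (the tar-pit
specimens are effectively modern; excluding sub-1-Ma rows steepens the slope
to 0.798), and `exclude` drops named records. The published summary numbers
themselves disagree (15%→58% in one place, 20%→50% and "about 5% per
10 Myr" in another, implying slopes of ~0.72 vs ~0.5 %/Myr); this package
does not arbitrate — the trend operation reports what the table supports and
the acceptance checks use ranges.

The %NC-versus-EQ profile bins specimens by EQ (default width 0.5) and
reports per-bin mean %NC, the overall maximum (80.76%, a chimpanzee
braincast; no mammal in the table exceeds 81% once the bad *Equus* cell is
recomputed), and a plateau edge: the smallest bin edge beyond which
successive occupied-bin means differ by less than 2 percentage points. On
the packaged table the profile climbs to ~78–80% by EQ ≈ 2 but the sparse
high-EQ bins jitter by 2–4 points, so no bin satisfies the strict plateau
rule and `eq_at_plateau` is `None` — the plateau is visible to the eye, not
to this conservative detector. Both bin width and tolerance are parameters.

## Brain–body polygons

`minimum_convex_polygon` is the convex hull (via Qhull) of log₁₀-transformed
(P, E) points, stored counter-clockwise from the lexicographically smallest
vertex with collinear vertices removed, so vertex lists are canonical and
comparable. Classification of a point is *inside*/*on_boundary* by convex
containment, otherwise *above*/*below* the polygon's upper/lower boundary
chain at the point's log₁₀ P — defined only within the polygon's horizontal
extent, else *outside_range*. Containment uses edge cross-products with a
1e−9 tolerance; tests cross-check it against shapely and check hulls against
an all-triples brute-force oracle.

`extend_polygon` continues the upper boundary rightward from the rightmost
upper vertex — by default at the slope of the last upper-hull edge, with the
theoretical 2/3 available by argument — and draws the parallel lower
boundary through the vertex of minimum log₁₀ E, then re-convexifies. The
vertex reading of "parallel lower boundary through the smallest brain sizes"
was chosen over a tangent-to-the-whole-polygon reading; the two differ only
when the minimum-E vertex is not on the lower-right chain. Extension is
monotone (never removes area) and always contains the original, property
tested over seeded random polygons.

The living-reptile comparison polygon cannot be rebuilt exactly: the
published per-specimen reptile data are not printed. `synthetic_data.
reptile_brain_body_points` therefore generates a documented synthetic
reptile cloud — intercept b = 0.005 (reptile-grade encephalization),
theoretical 2/3 slope, Gaussian log residuals (sd 0.12), body masses from
10 g up to the printed alligator maximum — and appends the two *printed*
crocodilian maxima (134 kg/15.6 g crocodile, 205 kg/14.08 g alligator) so
the upper-right boundary, the part that matters for boundary questions, is
pinned by real published values. Against this polygon, and against its
extension to log₁₀ P = 7, the least-encephalized mammal in the table
(*Arctocyon*, 7.14 ml at 16,144 g) classifies *above*: at that body mass a
2/3-slope line through the alligator point predicts ≈ 2.6 g of brain.

## Surface–volume scaling

`fit_surface_volume` is OLS of log₁₀ S on log₁₀ E. On noiseless data from
any exact power law it recovers the parameters to 1e−9 (tested with the
cortical-surface relation S = 3.75·E^0.91 and with spheres at exactly 2/3).
On the packaged table the endocast exponent is 0.661 (r = 0.987, n = 129) —
at, not above, the geometric reference. This is expected: an endocast's
surface excludes cortex buried in sulci and fissures, so it scales like a
smooth solid, whereas *true cortical* surface in living mammals scales near
0.91. The acceptance band (2/3, 1) extrapolated that cortical-surface
statement to endocast data, and the corresponding test is deliberately left
failing with this explanation rather than weakened.

The convolutedness index S / (c·E^(2/3)) uses a 2/3-pinned reference fitted
to the analysis dataset itself (log₁₀ c = mean residual), not a sphere,
because folding is judged against the dataset's own smooth-scaling trend.
It is invariant to dataset ordering and correlates positively (Spearman
ρ = 0.15) with volume across the table.

## Within-species variation

`cv_summary` uses the arithmetic mean and the sample (n−1) standard
deviation; the fixture pins this choice — the published SD of the eight
*Bathygenys* volumes (1.253082) is the n−1 value, the n formula gives 1.172.
CVs on the packaged table: volume 10.6%, surface 9.9%, neocortex 7.8%,
neocortex:surface ratio 6.5%. Percentages are reported to one decimal;
internal statistics are unrounded.

## Synthetic data

`generate_dataset` draws, per species: log₁₀ P uniform over a configured
range (default 10² – 10⁶ g, the packaged table's span); log₁₀ E on the
configured line (default α = 2/3, b = 0.12) plus Gaussian residuals
(default sd 0.1, matching the scatter of the real table); age uniform over
(−60, 0) Ma; and %NC either linear in age (default intercept 58%, slope
0.7 %/Myr — the packaged table's own trend) or saturating in the record's
true EQ (Michaelis–Menten shape, default plateau 80% with half-saturation
at EQ 0.5 — the simplest curve with the observed plateau behaviour; the
saturation's functional form is a modelling choice, not an estimate).
Surface areas are back-filled self-consistently (S−OB = 3.75·E^0.91, NC from
the %NC, OB = 5% of S−OB, S their exact sum) so every generated record
passes validation. Output is deterministic per (config, seed):
byte-identical CSVs.

`generate_within_species` draws lognormal volumes with σ = √log(1+cv²) and
μ set so the distribution mean equals the target — the lognormal keeps all
draws positive at any CV, and at CV = 0.10 it is practically
indistinguishable from the normal distribution described for real
within-species volumes.

What the generator does *not* emulate: phylogenetic correlation between
species (no trait evolution on trees), body-mass estimation error,
taphonomic missingness patterns, or measurement error correlated across
columns. Passing parameter-recovery tests therefore demonstrates estimator
correctness under the assumed structure, not robustness to the full
messiness of real fossil tables.

## Problem sizes and runtime

Defaults were chosen at desk scale: parameter recovery uses 100 replicates
of 200 species (the fitted slope lands within ±0.05 of 2/3 in 100/100
replicates; sd of the estimate ≈ 0.007), CV recovery uses n = 10,000
(±0.005), and the geometry oracle uses 200-point clouds with a vectorized
all-triples check. The full test suite runs in a few seconds on one CPU.

## Known limitations

- No phylogenetic comparative methods: species are treated as independent
  points, as in the historical analyses this package reproduces. Modern
  reanalysis should use PGLS or independent contrasts.
- The reptile polygon's left and lower extent is synthetic (documented
  above); only its upper-right anchors are published values.
- The missing 118th fossil row and the internally inconsistent printed cells
  are preserved as-is and flagged, not repaired.
- The plateau detector is conservative on sparse profiles (see above).
- Eq. P = 0.021·L^3.03 is for body length; no operation applies it to the
  table's endocast lengths.
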