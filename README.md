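# reeftraits

Analysis toolkit for tracking coral-reef community succession — how the
cover, species diversity and *functional trait* diversity of
reef-building corals change across repeated surveys, and what those
changes mean for reef fish.

It is written for reef ecologists working with standard monitoring
data: line-intercept transects (LIT) for benthic composition, and
belt-transect underwater visual censuses for fish. From those two
inputs plus a species × trait table, the package computes everything a
degradation/recovery study needs in one reproducible pipeline.

## What it computes

**Benthic cover.** LIT cover is a length ratio: cover of a category is
the summed intercepted tape length divided by the summed tape length,
so transects of different lengths pool naturally by length weighting.
Growth-form cover is aggregated through each genus's modal growth form
for records not identified to species.

**Diversity.** Hill numbers `qD = (Σ pᵢ^q)^(1/(1−q))` for q = 0
(richness), 1 (exponential Shannon) and 2 (inverse Simpson), with
Chao–Jost sample coverage
`Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁+2f₂)]` and rarefaction /
extrapolation curves (exact hypergeometric interpolation, Chao1-style
extrapolation capped at 2n).

**Assemblage structure.** Bray–Curtis distances, PCoA, PERMANOVA with
crossed fixed factors (year × protection, sequential sums of squares,
permutation p-values), and distance-based RDA with AIC forward
selection over the benthos/substrate categories.

**Trait space.** Seven habitat-forming traits (growth rate, skeletal
density, colony size, colony height, corallite width, intra-colony
space size, surface-area:volume ratio) are binned into ordinal 1–5
scores, turned into a Gower distance matrix and embedded by PCoA; the
first four axes are the trait space. Three assemblage metrics follow:

* *trait volume fraction* — convex-hull volume of the taxa present,
  relative to the pooled all-years hull;
* *5-NN functional redundancy* — mean summed distance of each taxon to
  its five nearest neighbours (lower = denser packing = more
  redundancy);
* *functional dispersion* (FDis) — cover-weighted mean distance to the
  cover-weighted centroid.

KDE occupancy maps with 0.5/0.95 probability-mass contours visualise
which parts of trait space each year occupies.

**Fish.** Abundances standardised to individuals per 60 m², split into
coral dwellers (CD) vs non-coral dwellers (NCD) and four body-length
classes, compared across years by ANOVA with Fisher's LSD letters, and
linked to coral cover with random-intercept linear mixed models (REML,
Wald t-tests with Satterthwaite degrees of freedom).

**Synthetic scenarios.** `reeftraits.synthetic` generates complete
surveys with known ground truth — a ~90-taxon coral pool built around
growth-form archetypes, cover trajectories with a
degradation-then-partial-recovery shape, and fish counts Poisson-linked
to coral cover — so the whole pipeline is testable end to end without
any field data.

## Worked example

```python
from reeftraits.synthetic import ScenarioConfig, generate_scenario
from reeftraits.pipeline import analyze_scenario

scenario = generate_scenario(ScenarioConfig(seed=1))
results = analyze_scenario(scenario, n_perm=999)
print(results["trait_metrics"].round(3))
```

```
      n_taxa  volume_fraction  volume_degenerate  redundancy_5nn  dispersion
year
2006      48            0.883              False           0.320       0.314
2010      50            0.371              False           0.142       0.255
2018      78            0.732              False           0.127       0.272
```

Reading the table: between the first and second survey the assemblage
lost the corymbose and branching corals that formed the vertices of
trait space, so the occupied volume collapsed from 88% to 37% of the
pooled hull even though richness barely changed (48 → 50). By the
third survey many encrusting and massive species had appeared: richness
jumped to 78 and the volume partially recovered (73%), but the new
species are near-duplicates of forms already present — the mean 5-NN
distance keeps falling (0.32 → 0.13), i.e. redundancy keeps rising —
and the corymbose corner of trait space stays empty, so the volume does
not return to its initial level. Dispersion is V-shaped and small
throughout because the dominant, high-cover taxa never change.

The same `results` dict carries the cover table, Hill/coverage
estimates, PERMANOVA and db-RDA tables, fish abundance summaries and
the fish–coral mixed-model fits. A command-line interface mirrors the
library:

```bash
reeftraits simulate --out-dir data --seed 1   # write survey TSVs + truth
reeftraits run-all --seed 1 --out-dir results # full pipeline + manifest
```

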