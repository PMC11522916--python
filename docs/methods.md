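# Methods

This note documents the models and procedures implemented in
`reeftraits`, the assumptions behind them, the numerical choices that a
user may want to question, and what the synthetic scenarios do and do
not establish about real survey data.

## Line-intercept cover and pooling

Cover from a line-intercept transect is the intercepted length of a
category divided by the tape length. When transects of unequal length
are combined (the emulated design mixes a single 50-m tape with six
10-m replicates), group cover is the ratio of summed intercepted length
to summed tape length — a length-weighted mean of per-transect covers.
We chose length weighting because cover *is* a length ratio; weighting
transects equally would give short tapes disproportionate influence.
Tape not assigned to any category is reported under an explicit
`unclassified` column rather than renormalised away, so the row-sum
invariant (100%) stays testable and incomplete field sheets are
visible. Field labels are normalised through a dialect map (a built-in
map covers common variants; users can supply their own).

Genus-level records ("Acropora spp.") are assigned the modal growth
form of their genus; modal ties break alphabetically on the form label
so repeated runs agree.

## Hill numbers, coverage, rarefaction

Hill numbers use the closed form `(Σ pᵢ^q)^(1/(1−q))` with the exact
exponential-Shannon limit at q = 1 (no numerical limiting). Sample
coverage is the Chao–Jost singleton/doubleton estimator. Interpolation
uses the exact hypergeometric expectation of the abundance frequency
counts, which makes the curve equal the observed Hill number exactly at
the reference sample size for every q; extrapolation uses the
Chao1-based richness extrapolator, the mixture form of the asymptotic
entropy estimator for q = 1, and the unbiased inverse-Simpson form for
q = 2, and is capped at twice the reference size where these
asymptotics are well behaved.

Line-intercept data give percent cover, not individuals, while
coverage and rarefaction are defined on counts. We discretise
intercepted length into pseudo-individuals at a declared resolution
(default 1 cm of tape = 1 individual, configurable via
`cover_to_pseudocounts`). The resolution affects the absolute sample
size and therefore the coverage value; at any realistic resolution the
pooled yearly assemblages sit in the >99% coverage regime, so the
diversity comparisons are insensitive to this choice. Fish use true
counts.

## Ordination and permutation tests

PCoA double-centres −½d², eigendecomposes, and scales eigenvectors by
√λ. Bray–Curtis matrices are generally non-Euclidean; by default axes
with λ ≤ 0 simply carry no coordinates and are excluded from the
explained-variance accounting, with the Cailliez constant-shift
correction available by option. For Euclidean-embeddable inputs the
embedding reproduces the input distances and the positive eigenvalues
sum to the total inertia (both tested at 1e-9).

PERMANOVA partitions tr(G) through nested projection (hat) matrices:
terms enter sequentially (Type-I) in the declared order year,
protection, interaction, each term's sum of squares being
tr((H_k − H_{k−1})G). Units are permuted freely (no strata) by
permuting the rows/columns of G, and p-values use the (b+1)/(B+1)
estimator, so the smallest attainable p with 999 permutations is
0.001. A seed is a required argument. If every unit is identical the
table degenerates gracefully (all term R² = 0, residual R² = 1). The
unit of replication is whatever matrix the caller passes; the pipeline
uses site-year units.

db-RDA regresses the PCoA coordinates (positive axes) on centred
predictors; constrained inertia is the sum of squares of the fitted
values. Forward selection minimises
`AIC = n·ln(residual inertia/n) + 2(k+1)` and stops when no candidate
lowers it. This residual-deviance analogue is stated explicitly
because "AIC for a constrained ordination" has no unique definition;
any alternative penalty changes where selection stops but not the
ordering of candidates. Candidates collinear with the selected set are
skipped and logged. Under pure-noise candidates this AIC retains the
null model in ≥90% of runs when the response has community-like
dimensionality (tens of taxa); with very low-dimensional responses the
maximum spurious R² over many candidates can beat the 2-point penalty
more often.

## Trait space and functional metrics

Seven traits are scored into ordinal 1–5 categories by fixed per-trait
cut points (shipped in `data/trait_breaks.tsv`); a value equal to a cut
point takes the lower category, and scoring is monotone by
construction. Missing raw values are filled before binning by
hierarchical geometric means — genus mean, then growth-form mean, then
global mean, computed on log-transformed values because the traits are
positive and right-skewed. This is a deliberate simplification of
regression/phylogenetic imputation; it is deterministic, auditable,
and adequate when (as here and in typical coral datasets) only ~10% of
cells are missing. Every imputed cell is flagged with the level used.

Gower distance over the ordinal scores divides each trait's absolute
difference by that trait's observed range and averages over traits;
zero-range traits are dropped with a warning rather than contributing
0/0. The trait space is the PCoA of this matrix with four retained
axes (configurable). The pooled all-sites-all-years taxon set defines
one fixed reference frame; per-year assemblages are subsets measured
inside it — the only construction under which the yearly volume
percentages are mutually comparable.

* **Volume fraction**: exact convex-hull volumes (Qhull) in the
  4-D space, subset hull ÷ pooled hull. A subset that is degenerate in
  4-D (fewer than five affinely independent taxa) returns 0 with a
  `degenerate` flag instead of raising, so a sparse year cannot abort
  a run. A convex hull, not a kernel hypervolume, is our declared
  reading of "occupied volume"; the KDE maps provide the
  density-weighted picture separately.
* **5-NN redundancy**: per taxon, the sum of Euclidean distances to
  its five nearest other taxa, averaged over taxa; presence-based (no
  cover weighting) because it is a purely geometric packing statistic.
  Neighbour ties break by taxon-label order.
* **FDis**: cover-weighted mean distance to the cover-weighted
  centroid, computed on the same 4-D coordinates as the other two
  metrics so all three share one geometry. Weighting by cover (rather
  than presence) is declared; it makes FDis reflect the dominant taxa.

KDE occupancy maps use a Gaussian kernel with Scott's bandwidth on a
grid padded around the reference-frame extent (shared canvas across
years). Contour levels are chosen so the superlevel set encloses the
requested probability mass; the 0.95 contour captures 95% ± 2% of
independent draws in testing.

## Mixed models and ANOVA

The linear mixed model supports one or two crossed random-intercept
factors — exactly the structures needed here (site; site + year) — with
REML estimation. The residual variance is profiled out and the
variance ratios are optimised on the log scale (positivity without
constrained optimisation) by Nelder–Mead from several starts; every
boundary configuration (some components exactly zero) is then checked
explicitly, so boundary estimates are found reliably and flagged.
Fixed effects are GLS at the REML estimates.

Satterthwaite degrees of freedom for a coefficient use
`df = 2g²/(∇g'A∇g)`, where g is the coefficient variance as a function
of the variance components, ∇g a central finite difference, and A the
inverse observed REML information (finite-difference Hessian of the
−2 log-likelihood on the natural variance scale). Components at the
zero boundary are excluded from the gradient, which recovers the OLS
df = N − p in the zero-variance limit; df is clamped above by N − p.
Year enters fixed designs as a categorical factor (three unevenly
spaced surveys); cover is analysed untransformed by default.

One-way ANOVA with Fisher's LSD post hoc: all pairwise t-tests on the
pooled mean square, run only when the overall F-test is significant,
with *no* multiplicity correction — that is the definition of LSD, and
it is flagged as such. Letters come from the maximal-interval display
on groups sorted by descending mean.

## The synthetic scenario

The generator emulates a three-survey monitoring programme: 8 sites
(4 inside a no-take area), one 50-m LIT per site in the first survey
and six 10-m replicates thereafter, and 2-m-wide belt fish transects
of 150/150/60 m. All randomness descends from one seed through named
substreams (traits, benthic, fish), so any stage regenerates
independently and identical seeds give byte-identical outputs.

*Traits.* ~90 coral taxa are drawn around eight growth-form archetypes
whose ordinal trait profiles were designed to span four structural
trait-space directions, with corymbose (minute corallites, open
colonies, high surface:volume) and branching (tall, large, light
skeleton) occupying two separable hull-vertex corners. Within-form
variation is mostly allometric — one shared size/rate factor per taxon
plus small trait-specific jitter — so congeners spread along a line
instead of inflating every axis; the forms that proliferate late in
the scenario (massive, encrusting, submassive) are tight clusters of
near-duplicates. Archetype means sit at ordinal bin centres so that
bin-flip noise is rare and the geometry is stable across seeds. About
12% of raw trait cells are masked to exercise imputation.

*Benthic trajectories.* Total coral cover runs 28% → 13% → 23% in
expectation (protected sites +4 percentage points in the final survey,
unprotected −4), with mean-one lognormal site effects (log-sd 0.7,
matching the large between-site spread typical of fringing-reef
monitoring). The species pools are 48 → 50 → 78 taxa: all corymbose
and branching taxa occur only in the first survey, and the third adds
many near-duplicate encrusting/massive taxa. Bare reef peaks in the
degraded survey and sand in the recovery survey, giving the db-RDA a
real substrate signal. Per-transect composition is Dirichlet around
the target (concentration 400), which guarantees intercepts never
exceed the tape.

*Fish.* ~30 taxa (12 coral dwellers) with per-taxon size-class
profiles. Expected density per 60 m² of each (dweller, size-class)
cell is a declining yearly baseline (totals 61.2 → 27.4 → 20.9, NCD
39.5 → 12.6 → 9.8) plus a slope × (site cover − year mean cover) term;
slopes are positive (0.25 ind./60 m² per percentage point) only for
large (>20 cm) non-coral dwellers and small (5–10 cm) coral dwellers,
and zero elsewhere. Centring on the year mean keeps the declared
totals as the expected yearly means while the coupling acts on
between-site contrasts, which is what the mixed model (site and year
random intercepts) estimates. Slope magnitude and the choice to survey
fish at all eight sites were set so the designed coupling is
statistically resolvable in a single scenario — the generator's job is
to produce a scenario in which the known effects are recoverable, not
a marginal one.

*What passing tests show — and don't.* The synthetic data share the
real data's structure (categories on a tape, counts on a belt,
ordinal traits) and its qualitative dynamics, but they are far cleaner:
taxa are perfectly identified, detection is perfect, transects are
independent Dirichlet/Poisson draws with no spatial autocorrelation,
and the trait archetypes are better separated than real congeners.
Pipeline correctness and estimator calibration transfer to real data;
effect sizes, p-values and the sharpness of the succession signature
do not.

## Numerical conventions

Permutation p-values are (b+1)/(B+1); permutation routines require an
explicit seed. Eigenvalues below 1e-10 of the leading eigenvalue are
treated as zero in PCoA and db-RDA. Hull degeneracy is decided by
affine rank at tolerance 1e-9. REML uses Nelder–Mead with xatol 1e-8
plus exhaustive boundary checks; variance ratios below 1e-10 are
reported as exact zeros. The LSD letter assignment, growth-form tie
break and nearest-neighbour tie break are all alphabetical/label-order
for determinism.

## Default problem sizes

The shipped analyses and checks run at the scale of the emulated
design — 24 site-year units, ≤90 taxa, ~8,600 intercept segments,
~900 fish records — with 999 permutations for reported tables. The
calibration studies use 1,000 replicates (PERMANOVA type-I error), 200
replicates (mixed-model recovery), 100 seeds (db-RDA selection) and 20
seeds (full-pipeline succession signature); these sizes give the
binomial margins needed to distinguish the claimed rates from chance
while keeping the whole suite to a few minutes on one CPU.

## Known limitations

Only random intercepts (no random slopes) are supported; Kenward–Roger
df, PERMDISP, pairwise post hoc PERMANOVA, bootstrap confidence bands
on rarefaction curves, and kernel hypervolumes are out of scope. The
Satterthwaite information matrix uses finite differences and can be
ill-conditioned exactly at variance boundaries (the boundary components
are therefore held out). The cover→pseudo-count conversion is a
declared convention, not an estimator of colony numbers; absolute
coverage values depend on its resolution even though conclusions here
do not.
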