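# Methods

This note records the models behind `cladespec`, the defaults and why they
are set where they are, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Scoring and ranking

Each metric is mapped onto 0–100 points by a linear min–max rescaling over
the species present for that metric (`score_mode = linear`); a
rank-percentile variant (`score_mode = rank`) is provided for sensitivity
analysis, since any monotone range-relative score is defensible and the two
agree in ordering. Metrics whose small values indicate specialization
(extent of occurrence, distinct ecoregions, plasticity) are inverted.

**EOO cap.** Range sizes are approximately log-distributed, so the widest
20% of ranges would otherwise stretch the scale and pile every remaining
species near 100. The `ceil(0.20·n)` largest areas therefore score zero
outright (ties at the boundary are all capped, logged), and the min–max map
is re-anchored on the remaining species. With n = 141 the cap covers
exactly 29 species. `cap_percentile` is configurable in [0, 1).

**Weights and missing data.** The final ranking is the equal-weight mean of
available scores: 4 metrics → 0.25 each, 3 → exactly 1/3 (not 0.33 — weights
must sum to one), down to a single metric. Missing metrics carry weight 0;
a species with no scored metric is excluded and logged. Missing is encoded
only as an empty cell or `NA`; no sentinel numerics, because the reweighting
depends on trustworthy missingness. In particular an **absent interaction
record is missing, not zero** — absence of a database record means nobody
looked; coding it as zero interactions would systematically push
under-studied species toward the generalist end. The literal-zero behaviour
is available via `interactions_absent_as_zero = true`.

**Metric model.** The default metric set is the four-metric model
(EOO, DEL, plasticity, interactions); the five-metric a-priori model with
domatia (20% each) is selected by `metrics = eoo_km2, del, plasticity,
interactions, domatia_total`.

## Metrics

* **EOO** is the area of the convex hull of the distinct occurrence points,
  computed after projecting with a spherical Lambert azimuthal equal-area
  projection centered on the point centroid, in km². An equal-area
  projection keeps areas comparable across latitudes; the projection is
  implemented directly (a few lines of spherical trigonometry) and verified
  against an independent spherical-excess computation in the tests. Fewer
  than three distinct points, or a point cloud whose projected PCA aspect
  ratio is below 1e-4 (a near-great-circle sliver), yields a missing EOO
  with a logged reason; the species keeps its other metrics.
* **DEL** assigns each occurrence point to the containing region polygon
  (boundary points count as inside; overlapping polygons resolved to the
  first by stable input order, with a warning) and counts distinct regions
  per species. Points outside every polygon are tallied and logged.
* **Plasticity** of a trait is the coefficient of variation of specimen
  values — sample (n−1) standard deviation over the mean, the standard
  dimensionless dispersion for positive traits; population-sd is a `ddof`
  option. A trait needs `min_specimens = 3` usable values. The species
  total is the **sum** of per-trait CVs over the configured trait set
  (default: petiole length, leaf length, leaf lobedness, specific leaf
  area); a mean option exists because summation vs averaging only rescales
  the ranking when trait coverage is complete, but differs under partial
  coverage.
* **Domatia** codes (0 none / 1 nonfunctional hairs / 2 functional) from
  three specimens are summed to 0–6; with fewer specimens the mean code is
  rescaled onto 0–6 and the deficiency logged.
* **Interactions** is the distinct-partner count per species.

## Selection and validation statistics

AICc subset selection fits ordinary least squares on every non-empty subset
of candidate metrics (complete cases per subset, intercept always included,
collinear subsets dropped) and ranks by AICc = AIC + 2k(k+1)/(n−k−1) with k
counting coefficients plus the error variance. Threat categories enter as
ordinal codes LC=0 … CR=4 with DD excluded — a deliberate least-squares
simplification (an ordinal model would need a link-function choice the
workflow does not otherwise require); the selected set is the union of the
best models for the threat and survey responses. Validation uses a
classical paired *t*, one-way ANOVA with Tukey–Kramer pairwise p-values
(studentized range with the unequal-n adjustment, via
`scipy.stats.tukey_hsd`) and a hand-written insert-and-absorb compact
letter display whose defining property — two groups share a letter iff
their comparison is non-significant at α = 0.05 — is re-checked by
reconstruction in the tests. Threat grades beyond NT can be pooled into a
single "threatened" group for three-group comparisons.

## Phylogenetic statistics

All methods are built on the BM tip covariance C (shared root-to-MRCA path
lengths), computed once per tree in an array representation.

* **Blomberg's K** is the observed MSE₀/MSE ratio about the phylogenetic
  GLS mean divided by its BM expectation; the permutation p shuffles trait
  values over tips (upper tail, observed included, seeded).
* **Pagel's λ** multiplies the off-diagonal covariance; μ and σ² are
  profiled out and λ optimized over [0, λ_max], where λ_max is the largest
  value keeping the matrix positive-definite (computed from the generalized
  eigenproblem, capped at 10); estimates above 1 are reported but flagged.
  The LR test against λ = 0 uses the 50:50 χ²₀/χ²₁ boundary mixture by
  default (plain χ²₁ optional). Estimates and log-likelihoods were
  cross-checked against R `phytools::phylosig` on a fixed 12-tip fixture
  (frozen in the tests).
* **ASR under BM** returns, for every internal node, the conditional
  expectation and variance of the node state given the tips, with σ²
  estimated by ML and the root estimate equal to the GLS phylogenetic mean
  (cross-checked against `phytools::anc.ML`). A singular tip covariance
  (zero-length edges, duplicate tips) gets a logged ridge of
  1e-8·tree-height.
* **PGLS** whitens by the Cholesky factor of C(λ) with λ fixed (0, 1) or
  estimated by ML; with an identity correlation it reproduces OLS exactly,
  which is also the exact λ = 0 reduction on an ultrametric tree.
* **Shift scan.** Full multi-shift OU estimation (EM or lasso over shift
  configurations) is deliberately replaced by a transparent greedy forward
  search: at each step every non-root edge is tried as one additional
  optimum shift under a common-attraction (α) OU model with the root state
  at the base optimum; α is profile-optimized on a log grid plus bounded
  refinement, the optima enter linearly and are solved by GLS. The step is
  kept only if the information criterion improves. The default criterion
  adds to BIC a multiplicity charge of 2·ln(#candidate edges) per shift
  (in the spirit of the mBIC/pBIC penalties used by multi-shift packages),
  and α is charged as a parameter only in shift models, where it first
  becomes practically identifiable from the mean structure — under a pure
  BM null it sits at the boundary. This combination holds the scan's
  false-shift rate on 50-tip BM data near zero while a planted shift of six
  stationary standard deviations is recovered essentially always (both
  rates are measured in the acceptance suite); plain BIC is available via
  `criterion="bic"` and is markedly more permissive. When α collapses to
  the lower bound in a shift model, the fit falls back to BM with shifted
  means and is flagged. Polytomies are handled natively; nothing is
  randomly resolved.

## Spatial statistics

Regional means average the final ranking over the distinct species assigned
to each region. Moran's I uses, by default, row-standardized inverse
great-circle-distance weights with a cutoff at the median pairwise centroid
distance — with no reported convention to follow, both this and queen
contiguity are provided and the scheme is recorded in the output. Inference
is by two-sided value permutation (default 9999, seeded), doubling the
smaller tail around the analytic null expectation −1/(n−1); islands (zero
row weight) are excluded with a warning.

## Synthetic data generator

The generator emulates the *shape* of a 141-species clade study: a Yule
tree rescaled to unit height; a latent specialization value evolving by BM
(or OU); and monotone links from the latent value to every metric —
log₁₀ EOO declining from 10^6.7 to 10^3.2 km² (so ~90% of species fall
below 2×10⁶ km², matching the heavy right skew such data show), occurrence
clouds whose hull is iteratively rescaled to the target area within 2%,
specimen trait tables whose per-trait CV declines from 0.45 to 0.07,
interaction counts rising log-linearly from 2 to 60, and domatia
probability rising with the latent value. Species centers drift toward low
latitudes as specialization rises, which plants genuine spatial clustering
for Moran's I to find. Occurrence-record counts are heavy-tailed (median
150, up to thousands — mimicking herbarium-aggregate record distributions);
specimen counts average 14.

**Survey scores** are modeled as the composite metric-based ranking a
species actually has — the generator runs the package's own metric and
scoring code on its noise-free outputs — plus a configurable additive
expert bias (default +13.6 points) and noise. Anchoring the survey to the
composite ranking, rather than to the raw latent value, is what makes the
bias an exactly recoverable parameter of a paired t-test; it encodes the
assumption that experts perceive the same multi-metric evidence the scoring
scheme aggregates. **Threat categories** come from thresholding the
(optionally noisy) latent percentile: the top 10.6% are threatened
(split CR/EN/VU), the next 10% NT, the rest LC; species stripped of three
or more metrics by missingness become DD. **Missingness** is applied per
metric at configured rates, preferentially to high-latent species (weight
0.25 + latent percentile), reproducing the real-world pattern that
data-deficient species tend to be the specialized ones.

What passing the end-to-end tests shows: the pipeline, run from written
files through metrics, capping, reweighting and ranking, recovers a known
monotone latent ordering (rank correlation ≥ 0.9 at zero noise), the
configured survey bias, and the built-in threat-group separation. What it
does not show: robustness to taxonomic synonymy, spatially biased sampling,
non-monotone metric–specialization relationships, or measurement error
structured unlike the simple noise models here — real occurrence and
herbarium data violate all of these in ways no generator of this kind can
certify against.

## Problem sizes and numerical choices

The simulation suites use a fixed 100-tip tree with 200 replicates for λ
calibration, a fixed 50-tip tree with 500 replicates for K and 100 each for
the shift scan's error rates, 2000 null replicates for the t/ANOVA type-I
checks, and one 141-species synthetic study — sizes chosen so the whole
suite stays desk-scale while Monte-Carlo error remains well inside the
asserted tolerances (±0.1 on λ and K, ±0.02 on type-I rates). The
reproduction script (`scripts/acceptance.py`) uses the same procedures at
half-scale replicate counts. Optimizers are bounded scalar searches seeded
by a coarse grid (21 points for λ, 10 log-spaced points for α), with the
grid optimum kept whenever refinement does not improve it; covariance
factorizations go through Cholesky with a logged ridge fallback; ML error
variances are floored at 1e-300 to keep log-likelihoods finite on exact
fits.

## Known limitations

* Species labels must agree after normalization (trim, collapse whitespace
  and underscore runs); no synonym resolution is attempted.
* The EOO is the spherical-projection convex hull only — no alpha hulls,
  no geodesic polygon clipping at the antimeridian (occurrence windows
  spanning ±180° longitude are not supported).
* The greedy shift scan explores one edge at a time and cannot represent
  compensating simultaneous shifts; it is a screening tool, not a full
  multi-shift estimator.
* AICc selection on ordinal threat codes treats category spacing as equal;
  the ordinal-logit alternative is not implemented.
* PGLS assumes the residual, not the predictor, carries the phylogenetic
  structure; measurement-error models are out of scope.
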