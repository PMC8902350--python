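# Methods

This note documents the statistical machinery, the choices made where
the procedure was genuinely open, and what the synthetic ground truth
does and does not establish.

## Census handling

A census row is one stem: multi-stemmed individuals are not merged. The
second-census status vocabulary (standing dead, broken, extracted
stump, or an A/D code) is collapsed upstream to a single binary dead
flag; recruitment between censuses is out of scope — the sample is the
stems alive at census 1. Cells are half-open intervals
`[k·cell, (k+1)·cell)` with stems exactly on the far plot boundary
clamped into the last cell. The edge buffer (default 25 m) is closed: a
stem exactly at the buffer distance is retained as a focal. Focal
species need at least 50 individuals in each of the three stages;
smaller per-stage samples make the stage-stratified fits unstable.
Excluded stems — edge trees, non-focal species — remain in every
neighbor pool.

## Stages and neighborhood indices

Stage thresholds are lower-closed/upper-open (a 4 cm shrub is an adult,
forced by the ≥ on the adult class), identical logic for all life
forms. Relative stage compares stage labels only, never DBH across life
forms: a juvenile shrub neighbor of a canopy sapling is "later".

The crowding index sums neighbor basal area over distance within a
closed ball (d ≤ r). Units are cm²/m and are never converted — the
index enters the models standardized, so units cancel. Neighbor pools
are the census-1 snapshot: stems that later died still compete, and all
species contribute. Coincident stems (d = 0) would make the 1/d kernel
singular; such neighbor pairs are excluded with a logged warning rather
than jittered, keeping results data-deterministic. The spatial-index
implementation (cKDTree, one pass for any number of radii, focal stems
processed in blocks of roughly two million neighbor pairs so memory
stays bounded on dense plots) is checked
against naive O(n²) evaluation to 1e-9 relative tolerance, and the
strata satisfy the partition identities Ea+Sa+La = CON (resp. HET) and
CON+HET = ALL exactly.

## Terrain and soil

Measured inputs are altimetry at the 20 m grid corners and ~1,310 soil
sample points; both are densified to the 5 m quadrat-corner lattice by
ordinary kriging (implemented here: empirical semivariogram,
weighted-least-squares fit of an exponential/spherical/gaussian model
with Cressie weights n/γ², nugget allowed, duplicate sample locations
averaged). The default model is exponential; with zero nugget the
predictor interpolates samples exactly. Per quadrat: elevation = mean
of four corners (the same convention is applied to soil surfaces);
convexity = center minus the mean of the 8 surrounding quadrats (NaN on
the lattice boundary, which the edge buffer removes from every focal
sample); slope = mean dip angle of the four corner-omitting triangular
planes; aspect = circular mean (unit-vector resultant) of the four
planes' downslope azimuths from north — arithmetic averaging of
azimuths would be wrong across the 0°/360° wrap. The aspect covariate
is cos(α) + 1.1 ∈ [0.1, 2.1]; a horizontal quadrat has no azimuth and
is assigned the midpoint 1.1, the least-informative value.

## The mixed-logit fitter

The mortality model has crossed random intercepts for species and 20 m
grid. The fitter maximizes a Laplace approximation to the integrated
likelihood:

1. **Inner problem.** For candidate SDs (σ_s, σ_g), the conditional
   mode of (β, u, v) maximizes the penalized Bernoulli log-likelihood
   by Newton iteration with step halving (the objective is monotone
   across iterations by construction). The crossed design keeps this
   cheap: the grid block of the Hessian is diagonal, so each step
   reduces to a dense solve of size (p + n_species) via a Schur
   complement, and the log-determinant needed by the Laplace correction
   factors the same way.
2. **β refinement.** The log|H_uu| term depends on β through the IRLS
   weights; profiling β through the joint mode alone attenuates fixed
   effects by O(1%) on binary data. After the joint mode converges, β
   is refined by Newton steps on the exact profile gradient
   (X'(y−μ) − ½ ∂log|H_uu|/∂β, using analytic leverages), re-solving
   the random-effect modes after each step. With this correction the
   fitter agrees with lme4's glmer to ~1e-4 on fixed effects and ~1e-3
   on variance components (asserted in the test suite).
3. **Outer problem.** (log σ_s, log σ_g) are optimized by Nelder-Mead
   (derivative-free, deterministic; bounds 1e-4–10, start 0.3 for both
   SDs, warm-started from neighboring models during subset
   enumeration). The β refinement runs once at the optimum — the cheap
   joint-mode profile steers the variance search. A fitted SD at the
   lower bound is reported as 0.
4. **Accuracy.** On small crossed fixtures the Laplace marginal
   log-likelihood is within 0.1 nats of full tensor Gauss-Hermite
   integration (an oracle written independently in the tests).

Wald SEs come from the inverse profile Hessian of the fixed effects at
the mode. AIC counts k = |β| + 1 + 2 (intercept and both variance
parameters); the paper-facing convention throughout is significance at
|β| > 1.96·SE, strict inequality. Non-convergence (outer budget
exhausted, or |β| > 30 signalling separation) is flagged honestly and
such fits are dropped from model sets downstream with a logged count.
Covariates are z-scored with the sample SD (n−1); a constant covariate
raises an error naming it.

## Model averaging and radius selection

All 2ⁿ covariate subsets (including the null model) are enumerated in
binary-counting order, with a guard at n = 16. Akaike weights are
computed over all converged models; variable importance is the summed
weight of models containing the variable. Averaging is over the
ΔAIC ≤ 2 group with weights renormalized. The default estimator is
*natural* (conditional) averaging — only models containing the variable
contribute, weights renormalized over them — with the revised
square-root form of the unconditional SE,
Σ w'_i √(SE_i² + (β_i − β̄)²); full-model averaging (absent = 0) and the
squared combination are available behind flags. The neighborhood radius
is selected before subset enumeration, per life form: the radius in
5–40 m (5 m steps) whose pooled CON + HET model has the lowest AIC,
ties broken toward the smaller radius.

## Per-grid mortality comparisons

Stage mortality is tabulated per 20 m grid (only grid × stage cells
with at least one census-1 stem), and stages are compared by the
Wilcoxon signed-rank test on within-grid differences. Grids lacking a
stage are dropped pairwise, zero differences are removed before
ranking, tied magnitudes are mid-ranked; the null is exact for ≤25
informative untied pairs and a normal approximation with continuity
correction otherwise. The statistic reported is W⁺ (rank sum of
positive differences); an all-zero difference vector has an undefined
p, reported as NaN.

## Synthetic ground truth

The generator emulates the study conditions: a 500 × 400 m plot, 30
species in three life forms (40% shrub, 30% subtree, 30% canopy
species), per-species Thomas cluster processes (Poisson parents,
Gaussian offspring, default 40 parents × 68 offspring × 15 m dispersal,
≈82,000 stems; offspring wrap on the plot torus so density stays
uniform), DBH = 1 cm + Exponential(rate 0.215/cm) giving a reverse-J
distribution with mean ≈5.65 cm and most stems under 4 cm, and smooth
environmental surfaces (Gaussian-filtered noise, 40 m length scale;
elevation 450 ± 60 m, TN 2.0 ± 0.4 g/kg, TP 0.45 ± 0.10 g/kg, pH
4.7 ± 0.2, moisture 0.30 ± 0.05) run through the same terrain
derivations the analysis uses.

Fates are drawn from the mixed-logit model itself. The default truth
has later-stage conspecific crowding +0.3 per SD, earlier-stage
conspecific −0.2, later-stage heterospecific −0.2, σ_species = 0.5,
σ_grid = 0.3, generating radius 15 m, and stage-specific baselines
(−2.0 / −2.2 / −2.45 logits for sapling / juvenile / adult) so baseline
mortality declines with stage. Two scaling conventions matter for
recovery scoring. Stage-admissible strata mean different neighbor sets
for different focal stages, so their per-SD effects are scaled within
stage groups; stage-independent covariates are scaled globally. And
scaling moments come from interior stems only: edge stems have
truncated neighborhoods and are never analyzed as focals, so this puts
the per-SD truth on the same scale a downstream per-stage analysis
standardizes to. Residual scale differences (focal-species filtering,
interior vs full-stage samples) leave signs and significance exact and
magnitudes approximate.

What the generator does **not** emulate: uneven species-abundance
distributions (all species are equally abundant, so the ≥50-per-stage
filter typically retains every species and the focal share is near
100%), habitat association between species and environment,
environment-dependent stem density, distance-kernel mechanisms other
than the 1/d index (no Janzen–Connell kernels — mortality is generated
directly from the fitted model's own form), and measurement error in
coordinates or DBH. Passing recovery tests therefore demonstrates the
pipeline's correctness and power under the model's own assumptions, not
robustness to their violation on real censuses.

## Problem sizes

The test suite's recovery checks use 20 replicates of the full-size
plot at reduced stem intensity (≈49,000 stems, ≈10,000 juvenile
focals) with a five-variable candidate set (32 models per replicate),
and 10 replicates for radius recovery over the 5–40 m ladder.
`scripts/acceptance.py` runs a single 400 × 300 m plot (≈29,000 stems)
at study stem density through the full pipeline with the environmental
candidate set reduced to elevation and convexity, keeping the largest
exhaustive enumeration at 2⁹ = 512 models; these sizes are the
package's default desk-scale configuration, chosen so a complete run
stays in the minutes range on one CPU while the per-SD effects remain
detectable at |z| ≳ 4.

## Known limitations

* The Laplace approximation shares lme4's small-cluster bias; variance
  components for factors with few observations per level are slightly
  attenuated.
* Ordinary kriging is isotropic with a single fitted variogram per
  surface; no anisotropy, no external drift.
* Radius selection uses the pooled-index model only, as a two-step
  procedure; it is not re-optimized jointly with the stratified
  candidate sets.
* The coincident-stem exclusion makes the index depend on coordinate
  resolution; plots with rounded coordinates may want a jitter policy
  decided upstream.
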