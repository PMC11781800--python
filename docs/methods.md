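# Methods

This note documents the models and procedures implemented in `bbpls`, the
assumptions behind them, the synthetic data generator used to validate
them, and the numerical and design choices made where more than one
reasonable option existed.

## PLS correlation

The core analysis is symmetric PLS correlation: with imaging scores `X`
(subjects × reduced dimensions) and behavior `Y` (subjects × items), both
z-scored across subjects with the sample SD (n−1; the scale cancels in
every reported correlation and covariance fraction), the cross-covariance
`R = Yᵀ X` is decomposed by SVD, `R = U S Vᵀ`. Composite scores are
`LX = X V` and `LY = Y U`; loadings are Pearson correlations of original
variables with the matching composite; covariance explained per component
is `s_k²/Σ s_j²` over the **full** singular spectrum (K = min(items,
reduced dimensions)). No deflation is performed — this is PLS correlation,
not PLS regression.

SVD leaves each singular-vector pair's sign free. We fix it so that the
behavior loading of largest magnitude is positive per component, which
makes a general-psychopathology-style first component (all items loading
positively) reproducible across runs and platforms. Degenerate quantities
(zero-variance composites) are reported as 0 with a flag rather than NaN.

The modality contribution of component *k* is the correlation between the
full imaging composite `X v_k` and the composite obtained after zeroing
every salience row outside one modality's column range. Two independent
equal-variance modalities driving a component equally therefore each
contribute 1/√2, not 1/2.

## Preprocessing

Confounds are removed per feature by OLS residualization. The base terms
are age, age², sex, acquisition site, and ethnicity (dummy-coded,
first-level reference — the choice of reference level is invisible to the
residuals). Surface area is additionally adjusted for total surface area;
thickness and volume for intracranial volume; connectivity (resting or
task) for mean framewise displacement and mean DVARS. Tract metrics use
the base terms, with motion optional. Residualization is idempotent and
produces residuals exactly orthogonal to the design.

By default the residualization coefficients are fitted on the full sample
before splitting, and the split subsamples inherit those residuals; the
transfer analysis separately re-fits everything on discovery subjects
only, because out-of-sample weight transfer must not touch replication
data. Both orders are available (`residualize_scope`), since the
literature rarely states which was used; the difference is small whenever
the split arms are demographically matched.

Items with zero variance in the analysis subset are dropped (a community
sample routinely produces items nobody endorses). The
discovery/replication split stratifies on site × sex × ethnicity ×
age-quartile × symptom-score-quartile cells, allocating `round(f·n)` of
each cell to discovery; singleton cells are merged upward by dropping the
last stratification variable rather than failing. "Overall symptom load"
for matching is the first principal component of the centered item
matrix, sign-fixed to correlate positively with the item total.

## Dimensionality reduction

Each modality is reduced separately by PCA (SVD of the column-centered
block), keeping the smallest number of components whose cumulative
explained-variance ratio reaches the threshold (default 0.5, closed
boundary). Features are centered but **not** variance-standardized within
modality: features within a modality share units, and the z-scoring that
matters happens later on `X` and `Y` jointly. A `standardize` switch
exposes the alternative. Per-component signs are fixed so the
largest-|loading| feature is positive. The stored means and loadings are
sufficient to transform unseen data without re-fitting, which is what the
transfer analysis relies on.

## Inference

**Permutation.** Significance of the leading components is assessed by
permuting behavior rows only within acquisition site (site composition of
the null is preserved exactly), re-computing the singular values, and
comparing at the same component index, with add-one smoothing
`p = (1 + #{null ≥ obs})/(1 + n_perm)` and BH-FDR across the tested
components. Permuted saliences are not Procrustes-realigned: the test is
over the singular values as observed. When the inputs are confound
residuals, a Freedman–Lane step re-residualizes each permuted behavior
matrix on the confound design. This matters: plain permutation of
residuals is measurably anticonservative (the observed statistic inherits
the aligned projection geometry of X and Y residuals, which permutation
destroys), and the package's calibration study showed ~8% type-I error at
the nominal 5% without the correction versus 4–5% with it.

**Bootstrap.** Loading stability uses resampling with replacement within
site (site sizes preserved). Each resample's components are sign-aligned
to the original solution by the sign of `u_kᵀu⁰_k`; components are not
re-ordered. Z = loading / bootstrap SD, two-sided normal p-values, BH-FDR
at q = 0.05, and 2.5/97.5 percentile CIs are reported. Connectivity-edge
loadings are averaged over network blocks (B + B(B−1)/2 blocks for B
networks; within-network blocks exclude the diagonal, and a network with
fewer than two regions has an undefined within block, reported as NaN and
excluded from FDR) before Z-scoring, to limit the number of comparisons.
A loading that is constant across resamples has SD 0 and infinite Z; it
is flagged and counted as significant rather than dropped.

Under a fully null generator the bootstrap Z-test is only approximately
calibrated: a noise component's direction is arbitrary, and conditionally
on it the "loadings" are coordinates of a random unit vector, not zeros.
With adequate `n_boot` (≥ ~200) and a realistic number of items the FDR
mask is nonetheless empty in the large majority of null replicates, which
the test suite checks.

## Out-of-sample transfer

Generalizability is measured by freezing everything estimated in
discovery — PCA coefficients, the means/SDs of the reduced imaging
columns and of the behavior items, and `U`, `S`, `V` — and applying it
unchanged to replication data: project, normalize with discovery
statistics, multiply by the discovery singular vectors. Out-of-sample
loadings are correlations of these cross-validated scores with the
normalized replication data; per-component `corr(LX_k, LY_k)` is the
cross-validated effect size, tested by within-site permutation of the
replication behavior. Items that became invariant in the replication arm
are removed from both `Y` and `U`, with the affected `U` columns
renormalized to unit length (logged). Self-transfer (replication :=
discovery) reproduces the within-sample composite scores exactly, which
the tests assert to 1e−8.

## Gradients

The group connectivity matrix (mean of per-subject matrices over the full
sample) is row-thresholded to the top 10% strongest connections per row
(diagonal excluded from the ranking; at fraction 1 no thresholding is
applied), converted to cosine similarity between thresholded rows, and
negatives are clamped to zero — the diffusion operator needs a
nonnegative affinity, and thresholded connectivity rows are predominantly
positive anyway. Diffusion map embedding applies the anisotropic
normalization `W' = D^{−α} W D^{−α}` with α = 0.5 (halving the influence
of sampling density), forms the random-walk operator, and takes its
nontrivial right eigenvectors, computed by a dense symmetric
eigendecomposition of the conjugated operator — deterministic, no
randomized solvers, appropriate for parcellations up to ~1000 regions.
With diffusion time t = 0 the eigenvectors are used unscaled. Gradients
are unit-normalized with the largest-|entry| sign convention; variance
explained is `λ_k/Σλ` over the retained nonnegative spectrum (default 10
gradients). A disconnected affinity triggers a warning and per-component
embedding. Procrustes alignment to a reference gradient set is a pure
orthogonal rotation (reflections allowed, no scaling) after column
centering; the rotation is stored and the unaligned solution remains
available.

## Spin tests

Spatial correlations between cortical maps are tested against spin nulls:
a uniform random rotation (QR of a Gaussian matrix, sign-corrected,
det +1) is applied to the left-hemisphere centroid sphere and its
x-mirrored counterpart to the right, and parcels are re-matched to
rotated centroids. Re-matching uses one-to-one minimum-distance
assignment, so every spun map is an exact permutation of the original
values; greedy nearest-neighbour matching (which duplicates ~10% of
parcels on a few-hundred-node lattice) is available as an option.
Subcortical parcels are excluded. p-values are two-sided with add-one
smoothing. For connectivity, per-parcel within- and between-network
loading summaries are the signed means of a parcel's edge loadings to
regions inside/outside its network (an absolute-value variant is
exposed), and the map-vs-gradient correlation table is FDR-corrected
across targets.

## Synthetic cohorts

The generator produces all the structure the pipeline consumes, with
ground truth recorded for recovery tests.

- **Geometry.** Each hemisphere is a Fibonacci lattice on its own unit
  sphere, one mirrored from the other; bilateral networks come from
  k-means on left-hemisphere centroids (17 cortical networks + 1
  subcortical group by default, degrading gracefully for tiny test
  parcellations). Smooth cortical maps are Gaussian random fields sampled
  at centroids, with a squared-exponential kernel whose FWHM is given in
  degrees of arc (default 20°); homotopic parcels are spatially close by
  construction, and subcortex is spatially unrelated to cortex.
- **Latent structure.** `n_latent` components (default 3) with
  per-component strengths (default 5/3/2). Behavior saliences are
  orthonormal with an all-positive first column (a general factor);
  imaging saliences are built from smooth parcel maps (morphometry) and
  smooth symmetric rank-2 edge patterns (connectivity), scaled to equal
  per-modality norm and symmetrically (Löwdin) orthonormalized — the
  minimal-perturbation orthogonalization, so the recorded truth stays
  close to the generating patterns. A component of strength *s*
  contributes `2·s·z_k` to each side in noise-normalized feature space
  against unit feature noise; the factor 2 maps strength units to a
  regime where a strength-2 component is still clearly recoverable at
  cohort scale (n ≈ 2000, ~100 parcels), emulating a study whose leading
  components are unambiguously significant.
- **Connectivity.** Per subject, `C_i = C0 + W_i + D_i + ‖D_i‖_F·I`:
  a backbone `C0` of global offset (0.10), within-network blocks (0.30),
  and a Gaussian kernel over a planted zero-mean 1D gradient (coefficient
  0.30 × `gradient_strength`); low-rank Wishart node-coupled noise; and a
  symmetric zero-diagonal term carrying the latent signal, the i.i.d.
  edge noise (SD 0.10, plus 0.04 structured), and edge-level confound
  effects. The diagonal compensation `‖D_i‖_F·I` bounds the smallest
  eigenvalue at zero, so every matrix is positive semi-definite **and**
  the off-diagonal edges remain exactly linear in the planted subject
  scores — which is what makes the recorded connectivity saliences an
  exact oracle. Edges are vectorized in a fixed order: lower triangle,
  row-major, diagonal excluded.
- **Items.** Ordinal responses come from double-thresholding a Gaussian
  propensity (graded-response style), default cut-points 0.8/1.8 so "0"
  is the modal response, as in community symptom ratings.
- **Confounds and sites.** Age, age², sex, anatomy (ICV/total area), and
  motion effects enter with magnitude `confound_strength` (default 0.5);
  site effects are additive mean shifts on features and item propensities
  with their own magnitude `site_effect_strength` (defaults to
  `confound_strength`). The separation exists because subject-level
  confounds injected before ordinal thresholding leave a small genuine
  brain–behavior association that linear residualization cannot fully
  remove — a faithful nuisance for robustness work, but the wrong null
  for calibration studies, which use site shifts only.

What the generator does **not** emulate: fMRI timeseries or scanner
physics, realistic questionnaire psychometrics beyond ordinal marginals
and planted factor structure, family/household structure, missing data,
or heavy-tailed imaging artifacts. Passing tests therefore demonstrate
the correctness and calibration of the machinery under a plausible data
geometry, not effect sizes or generalizability figures for any real
cohort; real imaging–behavior covariance is far weaker than the planted
defaults, and out-of-sample effect sizes in real data are accordingly
much lower than the within-sample ones.

## Validation studies and problem sizes

The validation module runs each study at a fixed size chosen to keep the
full suite fast while leaving no ambiguity in the outcome: salience
recovery at n = 2000 (100 parcels, 60 items, strengths 5/3/2, recovery
compared inside the retained PCA span, where the fitted salience lives);
permutation calibration over 500 null replicates (n = 300, 99
permutations); bootstrap CI coverage of a planted 0.6 item loading over
100 replicates (n = 1000, 200 resamples); gradient recovery on a
105-parcel cohort plus a 60-node ring lattice; spin calibration over 200
replicate pairs of independent smooth maps (99 spins) against the naive
parametric test; and the transfer contract on two 2000-subject arms
sharing one generative truth. `scripts/acceptance.py` re-runs all of them
from a single seed.

## Known limitations

- The bootstrap Z-test inherits the usual conditional-inference caveat
  under pure noise (see above); it is a stability measure, not an exact
  test.
- Covariance-explained fractions use the full singular spectrum; with
  heavily truncated PCA the tail changes and the fractions with it.
- The spin test assumes maps live on comparable spheres per hemisphere;
  parcel-level spinning is an approximation to vertex-level projection.
- `demographic_posthoc` reports Welch t and Pearson r per component
  without multivariate adjustment beyond FDR.
- The pipeline's replication re-analysis compares loadings on the shared
  item set only; items dropped in one arm are excluded from the
  crosswalk.
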