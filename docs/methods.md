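# Methods

This note records the models, conventions and design choices behind
`ufiber`, in the spirit of a statistical software methods appendix: what
is computed, under which assumptions, and which decisions were genuinely
open.

## Streamline classification

A streamline is an ordered polyline in world millimetres with a reference
voxel grid (integer dimensions plus a 4×4 NIfTI-style affine). Voxel
centers sit at integer indices; voxel *i* owns the half-open cube
[i − 0.5, i + 0.5) in voxel coordinates.

**Length filter.** Arc length is the sum of consecutive segment norms.
The short-association-fiber band is [5, 40] mm with *both bounds
inclusive* — the conventional reading of tracking length limits, which
state bounds without strictness.

**Mask membership.** A streamline joins a long-range (LR) bundle when its
polyline traverses any nonzero voxel of that bundle's mask. Membership is
decided by exact per-segment grid marching (Amanatides–Woo through the
half-integer cell boundaries) rather than by resampling points and
rounding: point sampling at any finite step can miss a voxel whose corner
the segment clips, whereas the marching enumerates exactly the cells the
continuous path passes through (ties on cell boundaries are measure-zero
for continuous inputs). The test suite holds this equal to an independent
brute-force segment/box-clipping oracle. Streamlines may join several
bundles — real LR masks overlap — and no exclusivity rule is applied.
Bundle voxel occupancy (for feature averaging) uses the same traversal;
feature averaging is the arithmetic mean over occupied voxels with NaN
voxels excluded and counted.

**MDF and QuickBundles.** The clustering metric is the minimum
average direct-flip distance between streamlines resampled to 12
equidistant points. Clustering is the single-pass scheme: streamlines are
visited in input order and join the *first* cluster whose running
centroid lies within the threshold (ties to the lowest cluster id), else
found a new cluster; a member is flipped to the orientation nearer the
centroid before being averaged in. First-fit with a fixed visiting order
makes the procedure deterministic, which the reproducibility contract
requires.

**Outlier rejection.** The published pipelines expose outlier removal as
a single opaque parameter (α = 0.6); the underlying toolkit procedure is
not documented in enough detail to re-derive. We therefore specify an
explicit multi-scale rule with the same interface: cluster the bundle at
a geometric ladder of 8 thresholds spanning [2, 16] mm, score each
streamline by the fraction of levels at which its cluster holds ≥ 5% of
the bundle, and keep streamlines scoring ≥ α. Gross outliers sit in tiny
clusters at every scale and score ~0; genuine fibers share clusters with
neighbours even at the tightest scales. On default phantoms the filter
removes every injected outlier and retains ≥ 99% of genuine fibers.

## Tensor model

Voxel-wise tensors are estimated from ln S = ln S0 − b gᵀDg by linear
least squares restricted to b ≤ 1500 s/mm² (the Gaussian tensor model is
a poor description at b = 3000; the outer shell is provably ignored — a
test corrupts it and asserts bit-identical output). Whether the original
tooling used ordinary or weighted LLS is not stated; we use one
reweighting pass with weights equal to the squared predicted signal,
which recovers near nonlinear-LS accuracy at a fraction of the cost.
Negative eigenvalues are clamped to zero before scalar derivation so that
FA = √(3/2)·‖λ − λ̄‖/‖λ‖ stays in [0, 1]; MD, AD, RD are the mean,
largest, and mean-of-two-smallest eigenvalues.

## Developmental regression

Features and TICV are z-scored with the sample SD (n − 1); age stays in
raw years so slopes read as SD/year. Sex is coded 0 = female, 1 = male,
making β1 the female age slope and β1 + β3 the male one — the worked
example in the tests: printed TICV coefficients β_age = −0.04 and
β_age×sex = +0.07 give a male slope of exactly +0.03 SD/year.

Robust fits use IRLS with Tukey's bisquare weight. Open choices pinned
here: tuning constant c = 4.685 (95% Gaussian efficiency — the universal
default when only the weight function is named), residual scale
MAD/0.6745 re-estimated each iteration, convergence on max|Δβ| < 1e-8
within 50 iterations, standard errors from the weighted-LS covariance
s²(XᵀWX)⁻¹ with the robust scale, and p-values from t with n − rank
degrees of freedom. An exact fit (zero robust scale) returns the OLS
solution. With the tuning constant sent to infinity the estimator
coincides with closed-form OLS to < 1e-8, and at the study sample size
the 95% CI for the age slope covers the truth in ≈ 95% of clean-noise
replicates, so the covariance choice is calibrated in the regime the
pipeline uses. The SAF-vs-LR effect comparison uses
t = (β_a − β_b)/√(se_a² + se_b²) against the standard normal: degrees of
freedom for a difference of two robust fits are not well defined, and at
n ≈ 616 the distinction is negligible.

FDR families: one Benjamini–Hochberg family per coefficient panel — all
pathway × feature cells within one term and tier — mirroring how effect
matrices are displayed and read. Optional TICV-interaction screening
(TICV×age, TICV×sex, TICV×age×sex columns retained only when
individually significant) reproduces the model-selection step that, in
the motivating analysis, ends with TICV as a purely additive covariate.

## Partial correlations and specificity

Inter-feature and inter-bundle correlations are partial Pearson
correlations across participants controlling age, sex and z-scored TICV:
both variables are residualized on [1, covariates] and the residuals
correlated, with p from t = r√((n − 2 − k)/(1 − r²)) on n − 2 − k df.

The specificity test asks, per LR pathway i and feature, whether the
Fisher-z-transformed correlation with its associated SAF exceeds the
*arithmetic mean of the z-transformed* comparison correlations (mean of
z-values, not a back-transformed mean — z is the variance-stabilized
scale on which averaging is defensible). The difference is divided by
SE = 1/√(N − k − 3), the standard error of a single z-transformed partial
correlation, giving a one-tailed Z-test with the direction fixed as
"associated > comparison mean". Dependence among correlations sharing
the LR pathway is deliberately ignored (no Steiger-type correction): the
statistic is an approximation that quantifies specificity, and the
simulations below show it is conservative at the null. FDR runs across
pathways within each feature × hypothesis family.

## Synthetic cohorts

The generator emulates the study conditions of a large developmental
cohort: n = 616 participants, ages uniform on [5.6, 21.9] years, sex
Bernoulli(279/616 male). TICV is driven by a small negative age effect
(−0.04 SD/yr) and a positive age×sex interaction (+0.07 SD/yr) plus
Gaussian noise scaled so the latent variable has roughly unit variance —
the diverging male/female trajectories the TICV sub-model should
recover. Default per-feature coefficients follow the developmental
pattern (diffusivities falling with age, FA/ICVF/ISOVF/ODI rising; males
with higher baseline MD/RD and lower FA/ICVF; faster male MD/RD decline
via the interaction), with a small deterministic tier offset so SAF and
LR effect sizes differ. No per-bundle raw feature means/SDs are published
for the motivating cohort, so the generative scales are conventional
(unit-variance z-scale features), not calibrated.

Cross-feature structure is a single-factor correlation (loadings on a
myelination/packing axis) guaranteeing positive semi-definiteness.
SAF–LR coupling uses two latent factors per participant: a global factor
with loading c (`coupling_nonassoc`) received by every bundle, plus a
per-pathway factor with loading √(a² − c²) shared by the SAF and LR tier
of that pathway. Associated pairs then share covariance a², non-associated
bundles c², and a = c is an *exactly exchangeable null* — the
configuration used to verify the specificity test's error rate. (A
construction that loads the pair factor with a directly would not be
exchangeable at a = c, which is why this parameterization was chosen.)
Contaminated participants (a configurable fraction < 0.5) have their
noise inflated ×10 across all bundles.

What the generator does **not** emulate: spatial partial-volume effects,
measurement covariance between overlapping SAF/LR masks, non-linear
growth curves, site/scanner effects, or NODDI signal generation (NODDI
features are synthesized at feature level). Passing tests therefore show
the statistics behave correctly under the stated generative model, not
that the acquisition-level confounds of real data are handled.

## Phantoms

Phantoms place tube-shaped LR masks (radius 2 voxels) along parallel
axes on a ≥ 20³ grid with a non-trivial origin, and U-shaped SAF arcs
crossing each tube at its axis. The arc radius is chord-corrected so the
*polyline* length equals the requested length exactly, and positional
jitter is a rigid translation clipped at 3σ (default σ = 0.2 voxels) —
length-preserving, so generator-recorded lengths are exactly what the
length filter measures, and the clipped translation guarantees every arc
still traverses its own mask. Distractors are confined to a slab far
below the tubes and intersect no mask; injected outliers are straight
35 mm streamlines that pass through the tube but deviate grossly from
the U shape, spaced ≥ 18 mm apart so they cannot cluster with anything
at any ladder scale. Truth labels are therefore assigned by construction,
and classification accuracy against them is a genuine end-to-end check.

## Problem sizes and numerical conventions

Simulation-based checks use: 100 random designs for the IRLS/OLS
equivalence; 1000 random p-vectors (length ≤ 12) for the FDR oracle; 100
small phantoms for the traversal oracle; 500 replicates at n = 616 for
CI coverage; 100 replicates for the contamination comparison; 20 seeds
(6 pathways, n = 616) for the specificity null and 5 for power; 20
phantoms for outlier-filter scoring. These sizes make the whole
validation run in well under a minute while leaving Monte-Carlo error
small relative to every margin tested.

Numerical conventions worth knowing: Fisher z clips |r| to 1 − 1e-15;
partial correlations declare zero residual variance at 1e-10 of the
input norm; constant covariate columns collapse into the intercept; the
regression batch records failed cells (e.g. zero-variance features) with
NaNs rather than aborting; and all generators are bit-reproducible from
their seed, with pipeline stages seeded hierarchically from one master
seed.

## Known limitations

- The bisquare estimator's advantage over OLS under *symmetric*
  contamination is a variance (not bias) effect: with 10% of
  participants' noise inflated ×10 it wins about 80% of head-to-head
  replicates (and essentially always under grosser, ×100 contamination).
  Symmetric contamination leaves OLS unbiased, so per-replicate win
  rates cannot approach 1 at moderate inflation.
- The specificity Z-test ignores dependence among correlations sharing
  the LR bundle; simulations show it conservative under the exchangeable
  null, but its nominal level is approximate by design.
- First-fit QuickBundles is order-dependent (deterministically so);
  cluster counts can in principle be non-monotone in the threshold,
  though they are monotone on the phantom bundles tested.
- The tensor fit assumes single-compartment Gaussian diffusion below
  b = 1500 s/mm²; no NODDI fitting is provided.
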