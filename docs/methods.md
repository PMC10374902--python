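# Methods

This note documents the models and numerical choices behind the package: the
connectopic-mapping chain itself, the synthetic phantom that serves as its
validation surface, and the places where the design was genuinely open.

## Connectopy estimation

**Standardization.** Every voxel time series is z-scored (ddof = 1).  A
zero-variance voxel is an error at this stage by design: "insufficient
variance" is a QC condition, and the exclusion rules in
`connectopy.preproc` are the place to handle it, not a silent fill-in.

**Lossless SVD reduction.** The out-of-ROI data matrix (time x N) is replaced
by `U S` from its economy SVD, keeping singular values above `1e-10 * s_max`.
Since `U S = X V` with orthonormal `V`, all inner products among voxel-wise
covariance fingerprints — hence all distances the similarity step consumes —
are preserved exactly while the column count drops from N (often tens of
thousands) to at most T - 1.  `svd_reduce(..., return_basis=True)` also
returns `V`, which maps component-space fingerprints back to voxel space
exactly (`F_vox = F_comp @ V.T`).  This matters for one subtlety: the
eta-squared coefficient is *not* invariant under rotation of the profile
coordinates (its grand-mean term changes), so claims about losslessness are
made — and tested — by mapping back to voxel space rather than by comparing
eta-squared values computed in the rotated basis directly.

**Fingerprints and similarity.** Fingerprints are Pearson correlations
between ROI voxel series and the SVD component series.  Similarity uses the
eta-squared coefficient of the original connectopic-mapping literature (one
minus within-pair variance over total variance; 1 = identical profiles); a
plain correlation kernel is available behind `similarity="correlation"`.

**Spectral embedding.** The dense similarity matrix with zeroed diagonal is
the graph adjacency; no sparsification by default (an optional symmetrized
k-nearest-neighbour mode exists for large ROIs).  The generalized problem
`L v = lambda D v` is solved through the symmetric normalization
`D^{-1/2} L D^{-1/2}`, eigenvalues sorted ascending.  The trivial eigenvector
is detected by `lambda < 1e-10` together with a coefficient of variation
below `1e-6` and discarded; the next eigenvectors are min-max scaled to
[0, 1].  Graph connectivity is checked first (a disconnected graph is an
error naming the component sizes), and near-degenerate leading eigenvalues
are recorded as a warning on the returned map, since the embedding
orientation is unstable there.

**Alignment and QC.** Eigenvector sign is arbitrary, so each map is
correlated with a reference (the planted gradient for phantoms; a
user-supplied reference map otherwise) and flipped (`v -> 1 - v`) when the
correlation is negative.  A subject passes reference QC iff the post-flip
correlation is at least 0.5; all exclusion comparisons in the package
(motion, variance, reference) are strict inequalities.

## Trend-surface model

The design contains per-axis monomials only — `(1, x, y, z, x^2, y^2, z^2,
...)`, no cross-terms — over coordinates standardized per axis (mean 0,
sd 1) before powering, which makes coefficients unit-free and comparable
across subjects whether voxel indices or world mm coordinates are supplied.
An axis that is constant inside the ROI is dropped with a warning rather
than raising, because thin ROIs occur in practice.

Fitting is OLS; when the design's condition number exceeds 1e10 a ridge
solve with `lambda = 1e-8` takes over (bias negligible, stability restored).
`BIC = n ln(RSS/n) + p ln(n)` with `p = (1 + 3k) + 1` counting the
intercept, the coefficients and the noise variance.  Two numerical guards:

* RSS is floored at `1e-15 * TSS` inside the logarithm, so noise-free
  surfaces (RSS at machine precision) keep a finite BIC and the parsimony
  penalty, not floating-point rounding, decides between orders that both fit
  exactly.
* `select_order` scans orders 1..max; an order whose design is
  rank-deficient on the ROI's geometry (e.g. sixth powers on a grid with
  only six distinct coordinate levels per axis) is marked infeasible
  (BIC = inf) with a warning instead of aborting the scan.

Order selection is the global BIC minimum, ties broken toward the lower
order; the full BIC/EV table is always returned so the fit/parsimony
trade-off can be audited.  Explained variance is `1 - RSS/TSS`.

## Dual regression

Stage 1 regresses each timepoint's ROI pattern onto the demeaned spatial
map(s) plus an intercept, across voxels; stage 2 regresses every brain
voxel's series onto the stage-1 time courses plus an intercept.  Time
courses are variance-normalized between the stages (switchable), which
absorbs any positive rescaling of the input map — the projections are scale
equivariant.  A map orthogonal to the data yields an exactly zero time
course; the normalization explicitly guards against inflating such
numerically null time courses.

## Inference

* **Associations.** Per TSM term, both the coefficient and the score are
  residualized on `[1 | covariates]` by OLS; the partial correlation of the
  residuals is tested with `t = r sqrt((n-2-q)/(1-r^2))` on `n-2-q` degrees
  of freedom.  Categorical covariates (sex, site) are dummy-coded with the
  alphabetically first level as reference.  Subjects with missing scores or
  covariates are dropped listwise with a logged count; imputation is out of
  scope.
* **Multiplicity.** Holm's step-down procedure at FWER 0.05.  The default
  family is the set of terms supplied in one call — i.e. one
  (score, ROI, condition) combination; wider families are the caller's
  choice by passing the corresponding p-values together.
* **Group/condition contrasts.** Independent two-sample t (pooled variance
  by default, Welch optional) and paired t on within-subject differences;
  a term whose paired differences have zero variance but non-zero mean
  raises instead of reporting an infinite t.
* **Voxel-wise GLM.** Per-voxel OLS t for a chosen contrast column; FWE
  control by max-T permutation of that column (seeded, 1000 permutations by
  default), which respects the spatial correlation among voxels that makes
  Holm conservative there; Holm remains available.
* **Score-conditioned reconstruction.** Per-term OLS lines of coefficient on
  score predict a full coefficient vector at any score point; the surface is
  rebuilt from the TSM basis and compared with the cohort-average surface by
  RMSE over the z-axis terms (the canonical gradient direction).  Because
  OLS lines pass through the sample means, the RMSE-to-average profile is
  V-shaped with its minimum at the cohort's mean score; the validation
  probes three increasing points from the low end of the scale up to the
  cohort mean, which mirrors the situation where the cohort-average gradient
  corresponds to the upper (well-differentiated) end of the behavioural
  scale.  With no planted coupling the fitted slopes are near zero and the
  profile is flat in comparison.  Points outside the observed score range
  warn about extrapolation rather than erroring.

## The synthetic phantom

The generator emulates exactly the structure the pipeline is built to
detect, with everything else stripped away:

* Geometry: a small grid (default 12 x 8 x 12) holding a 6 x 6 x 10 ROI and,
  beyond it along x, K = 4 contiguous out-of-ROI slabs, one per "network";
  brain mask = ROI union slabs.
* Network time courses: Gaussian white noise smoothed with a width-3 moving
  average (band-limited, BOLD-like autocorrelation without an HRF model),
  then sample-orthonormalized by QR and standardized.  Orthonormalization is
  deliberate: with only K = 4 courses, random sample correlations of about
  +-0.1 would warp the planted fingerprint geometry enough to reorder
  adjacent gradient levels, making ground truth ambiguous.
* Planted gradient: ROI voxel i mixes the networks with Gaussian bump
  weights `w_k(g_i) = exp(-(g_i - c_k)^2 / (2 sd^2))`, centres equally
  spaced on [0, 1] and `sd = 1/K`.  At this width adjacent centres sit
  about 1.3 sd apart, so neighbouring networks genuinely overlap and the
  topography is smooth; narrower bumps (e.g. half this width) were found to
  produce an effectively parcellated ROI whose similarity graph falls apart
  into per-network cliques — the opposite of what a connectopy models.
* Flatness: `g_i = 0.5 + theta (p_i - 0.5)` compresses the gradient around
  its midpoint.  Because each estimated map is min-max rescaled, flatness
  expresses itself through signal-to-noise: at fixed noise sd the fitted
  linear-z magnitude increases monotonically with theta (the package's
  flatness-ordering property), which is how "gradient flattening" becomes
  measurable in the TSM coefficients.
* Cohorts: per-subject theta ~ U(0.3, 1.0) (cases optionally shifted),
  `score = 70 + b theta + N(0, sd)` on an adaptive-behaviour-like scale,
  age ~ N(17, 5) years, two-thirds male, three sites; one independent RNG
  stream per subject derived from (seed, subject index), so subjects are
  decoupled and every output is bit-reproducible from the seed.

What the phantom does *not* emulate: haemodynamic convolution, task designs,
head motion, spatial autocorrelation of noise, registration error, and
multi-scale fingerprint structure of real grey matter.  Passing the phantom
suite therefore demonstrates the correctness of the algorithms and the
recoverability of a planted topography under Gaussian noise — not
performance on real clinical data.

Default validation conditions: T = 200 volumes at TR 2 s, noise sd 0.5
(roughly half the ROI signal's scale), theta = 1, K = 4.  The standard
phantom run recovers the planted gradient with |Spearman rho| around 0.99
and never below 0.9 across seeds; noise-free recovery is exact (the test
rounds map values to 1e-9 before ranking, since voxels that are exactly tied
in the planted gradient agree only to about 1e-13 in the eigenvector).

## Preprocessing and QC conventions

* High-pass filtering regresses out a discrete-cosine drift basis (all DCT
  regressors below the cut-off plus the constant) instead of an IIR filter,
  avoiding edge transients on short runs.  The documented stage order is:
  filter data *and* confounds with the same basis, then nuisance-regress —
  in that order the sequential result equals the joint projection onto the
  concatenated design exactly.
* Framewise displacement uses Power's formulation, `sum |d trans| +
  r sum |d rot|` with a 50 mm head radius (configurable), rotations-first
  column order by default (switchable, since conventions differ).
* Exclusion defaults: mean FD > 0.7 mm, max FD > 3.8 mm, ROI variance floor
  1e-6 (on standardized data "insufficient" means numerically zero),
  reference correlation < 0.5.  All strict comparisons; re-applying the
  rules to the retained table is a no-op.
* Mask erosion uses the 6-connected structuring element and refuses to
  return an empty mask.

## Problem sizes used in the validation suite

The shipped tests and `scripts/acceptance.py` run on deliberately small
instances chosen to exercise every code path with tight tolerances: phantoms
with 360 ROI voxels and T = 120-200; 20 phantom seeds for gradient recovery;
graphs up to 50 nodes against the dense generalized eigensolver; 50 seeds
for BIC order recovery; 200 simulated cohorts each for association
calibration and power (n = 60, 18 terms); cohorts of 24 phantom subjects for
the score-conditioned RMSE profile.  These sizes are the package's reference
validation conditions; all of them regenerate from the seed passed on the
command line.
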