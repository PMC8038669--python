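# Methods

This note documents the models, parameter choices and numerical decisions
behind `octa_density`, and what the synthetic benchmarks do and do not
establish about clinical data.

## Image quantification chain

**Inputs.** Square grayscale en-face angiograms in [0, 1] with a physical
field of view (default 6 × 6 mm, nominally 500 × 500 px, ≈ 12 µm/px), one
per plexus (SCP, DCP). Acquisitions with a scanner-reported signal strength
below 8 (0–10 scale) are rejected before any processing; images without a
score — all synthetic images — are admitted.

**Resampling.** Both images are bilinearly resampled to a canonical
1024 × 1024 grid so that every pixel-unit parameter below has a fixed
physical meaning (≈ 5.9 µm/px at 6 mm). Resampling at the target size is
the identity.

**Equalization.** Global histogram equalization over 256 bins, implemented
as the exact step mapping `v ↦ CDF(bin(v))`. The step form matters: an
interpolated equalization (as in `skimage.exposure.equalize_hist`) assigns
distinct outputs to values inside one bin and thereby stretches the faint
point-spread shoulder around each vessel to near-full contrast, which no
subsequent threshold can undo. With the step mapping, everything dimmer
than 1/256 of full scale collapses to the background level.

**Vesselness.** Frangi-type response from the eigenvalues |λ₁| ≤ |λ₂| of
the scale-normalized (σ²-weighted) Gaussian Hessian at σ ∈ {1, 1.5, 2} px,
bright-vessel convention (response zero where λ₂ ≥ 0):

    V = exp(−R_b² / 2β²) · (1 − exp(−S² / 2γ²)),  R_b = λ₁/λ₂,  S = √(λ₁²+λ₂²)

maximized over scales and normalized to [0, 1] per image. Two non-standard
constants, both fixed on the noise-free recovery harness before the
acceptance thresholds were evaluated:

* `γ = 2.0 · max(S)` per scale (conventional choice is 0.5). With the
  conventional value the structureness term saturates and the response on
  the weak-curvature shoulder flanking each vessel is as large as on the
  crest; the larger γ keeps the response ∝ S² there, so one global
  threshold separates crest from shoulder. β = 0.5 as usual.
* a numerical floor: responses with S < 10⁻³σ² are set to exactly zero.
  Gaussian derivative kernels on a constant image return second
  derivatives of order 10⁻⁴–10⁻⁵ rather than zero; without the floor a
  structureless image would normalize that noise to a full-scale response.

**Noise floor and binarization.** The threshold is the 95th percentile of
the response over the background candidate set, defined as pixels whose
response lies in the lowest quarter of the response *range*
(`min + 0.25·(max − min)`). A pixel-rank definition of the candidate set
was considered and rejected: whenever more than a quarter of the pixels
have exactly zero response — true of every clean image — the rank cutoff
collapses onto the minimum and the estimated floor is 0, so the strict
`response > threshold` binarization admits arbitrarily faint responses.
The range-based set degrades gracefully: an all-equal response returns
that value, and on noisy images it behaves as a conventional background
percentile. Components smaller than 10 px (8-connectivity) are then
removed; the cleanup is idempotent.

**Projection-tail removal (DCP only).** Superficial flow duplicated into
the deep slab is removed by gated subtraction: at SCP-mask pixels,
`DCP ← clip(DCP − g·SCP, 0, 1)`. The gain g is the median of per-pixel
DCP/SCP ratios over SCP-vessel pixels. An ordinary least-squares slope is
biased upward by genuine deep vessels running beneath superficial ones
(on synthetic data, g ≈ 0.85 fitted for a true contamination of 0.6),
which over-subtracts and fragments the deep network at crossings; the
median ignores that minority and recovers the true gain exactly when the
contamination is purely proportional. A fixed-gain mode is available.

**Density measures.** MPD is the mask mean, reported in percent
(0 = avascular, 100 = fully perfused). MVD is the length of the
topology-preserving skeleton per unit area: orthogonal neighbour links
count one pixel-length, diagonal links √2, isolated pixels one; a
pixel-count convention is provided as an option (it rescales MVD by
roughly 1/1.08 on isotropic networks but preserves ordering). The
absolute MVD scale of the original instrument software is not anchored
(its printed values carry a % sign while being defined as unbounded
length/area); comparisons should therefore be relative, which is how the
cohort statistics use them.

## Synthetic angiograms

Vessel networks are drawn as branching random walks: walkers start on the
border (heading inward) or in the interior, advance in unit steps with
Gaussian angular jitter (σ = 9°), stamp disks of their calibre (1–4 px at
the 500-grid, ≈ 12–48 µm) along the way, and branch with probability
0.015/step at ±35° up to a budget of 500 walkers. A walker older than 8
steps that meets an existing vessel anastomoses with it (stops) with
probability 0.3, else crosses — crossings are genuine in an en-face
projection of a three-dimensional plexus. Defaults (120 seed walkers)
give a truth perfusion density around 15 % and a truth skeleton density
around 18 mm/mm², the scale of clinical MVD readings.

The observed image is the mask under multiplicative uniform speckle
(±30 % by default; 0 for the noise-free benchmarks) followed by a
Gaussian blur of σ = 0.8 px. Ground truth: `truth_mpd` is exactly the
mask mean; `truth_mvd` is the length of the *rasterized centerline
union* per unit area — summing the walked lengths would double-count
crossings that no image-based estimate can observe. Cyst-shaped dropout
(axis-aligned random ellipses clearing mask, image and centerline)
emulates the avascular spaces of intraretinal fluid; projection tails are
composited as `clip(DCP + α·SCP, 0, 1)` with the truth untouched.

What the generator does **not** emulate: additive background decorrelation
noise in avascular areas (background is exactly zero, which is why the
noise-free benchmarks are the stringent ones for the threshold), true
capillary-free zones around arterioles, the foveal avascular zone,
segmentation errors, and motion artifacts. Recovery results on these
images bound algorithmic error, not clinical accuracy.

**Ground-truth recovery (frozen defaults).** Over 20 noise-free networks
spanning seed counts 30–200 — a cohort-like density range; at fixed
density the across-seed spread of truth MVD is only a few percent and a
rank correlation would measure noise — the chain achieves a median
absolute MPD error of ≈ 3 pp (acceptance bound 5 pp) and a Spearman
correlation of ≈ 0.97 between estimated and true MVD (bound 0.9). The
tail-correction benchmark uses the clinically relevant configuration
(sparse DCP beneath a dense SCP, α = 0.9): there the uncorrected DCP
estimate roughly doubles and the correction restores it to truth. With
equally dense plexuses the equalization-plus-relative-threshold chain
already discounts the (dimmer) tails and the paired comparison is
uninformative — a known limitation of gauging correction quality by MPD
alone.

## Synthetic cohorts

One row per (eye, timepoint); 22 IRF ± SRF and 11 SRF eyes at T0 and T1,
11 healthy controls at T0 only. Per-eye densities are drawn as
`mean + SD·z` per (group, plexus, metric, timepoint) from the published
group summaries, with the T0/T1 draws of one eye correlated at ρ = 0.7
(repeated measures of the same retina; affects only variance components,
not means). The z draws are clipped at ±2.2 so that the most variable
group (DCP MPD during exudation, 20.7 ± 7.8) cannot produce negative
densities; with `recenter=True` (default) each group sample is affinely
rescaled to the exact target mean and SD, which restores the nominal
scale and makes the downstream estimates exact. Covariates use fixed
compositions (e.g. exactly 13/22 eyes with atrophy) rather than per-eye
Bernoulli draws, so the synthetic cohort reproduces the published counts;
covariates are drawn independently of the densities because only marginal
prevalences are published. Neovascular-subtype proportions are not
published and are set once to 0.6/0.2/0.2 (type-1 dominant). Treatment
variables are "none" for healthy eyes and the prior-injection count is
zeroed for treatment-naive eyes.

## Cohort statistics

**Baseline (T0).** Each factor is screened in a univariable OLS of the
outcome on that factor alone; reference levels are healthy (group),
female (sex), type 1 (subtype), aflibercept (molecule), naive (regimen).
"Not applicable" levels are treated as missing, so treatment factors are
fitted on treated eyes only. Factors with any level at p < 0.1 enter the
joint OLS; the fluid group is always retained as the exposure of
interest. Factors defined only for diseased eyes can never join the
multivariable model: restricted to their rows the healthy reference level
is absent and the group dummies are collinear with the intercept. On a
recentered cohort the group estimates equal differences of the published
group means exactly (e.g. SCP MPD: 37.4 − 44.4 = −7.0).

**Time effect.** Linear mixed model per group and outcome: fixed effects
timepoint + age + fibrosis + atrophy, random intercept per eye, REML
(statsmodels MixedLM); covariables that are constant within a group are
dropped. On a balanced cohort with time-invariant covariables the
timepoint coefficient equals the mean within-eye T1 − T0 difference
regardless of the variance estimates — the closed-form oracle used in the
tests. Confidence intervals and p-values use a Wald t statistic with
n_eyes − 1 degrees of freedom; other df conventions change the intervals
slightly but not the estimates, and only estimates are benchmarked.
Report tables round to one decimal; all internal comparisons use full
precision. No multiple-testing correction is applied.

## Problem sizes and determinism

Defaults throughout are the study conditions: 44-eye cohorts, 500² input
images, 1024² canonical grid. The test suite runs the image benchmarks at
those sizes with 20 networks for recovery and 3 pairs for the tail
comparison; the pipeline tests use reduced cohorts (2–3 eyes/group) and
128² grids as smoke tests. Every random draw flows from a single integer
seed through `numpy.random.default_rng` / `SeedSequence`; identical seeds
give bit-identical images, cohorts and run manifests (file content
hashes). `scripts/acceptance.py --seed N` regenerates the recentered
cohort from N and refits the mixed models; because recentering fixes the
sample moments, the reported coefficients are seed-invariant by design
while still being computed through the full estimation path.

## Known limitations

* The original instrument algorithm is proprietary; this is a faithful
  reconstruction of its published steps, not a bit-exact clone, and its
  absolute densities will differ from instrument readings.
* MPD accuracy on synthetic data partially reflects a false-positive /
  false-negative balance (threshold bias inward, curvature-support bias
  outward); per-pixel segmentation quality is not the validated claim.
* The mixed model supports exactly two timepoints; longitudinal designs
  with more visits need a different model.
* Estimates of the tail-correction gain assume a spatially constant
  contamination coefficient.
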