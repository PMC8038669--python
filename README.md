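# octa-density

Quantification of retinal capillary perfusion on OCTA en-face angiograms,
with a synthetic benchmark and the cohort statistics used in exudative
age-related macular degeneration (AMD) studies.

Optical coherence tomography angiography (OCTA) images retinal blood flow
without dye injection. In exudative AMD, intraretinal fluid (IRF) and
subretinal fluid (SRF) displace and obscure the capillary beds; a central
clinical question is how much of the capillary network in the superficial
(SCP) and deep (DCP) capillary plexus is lost during exudation and how much
reperfuses after anti-VEGF treatment resorbs the fluid. This package is for
researchers who want an open, tested implementation of the two standard
density metrics and of the statistical workflow used to compare diseased
and healthy eyes across timepoints.

## What it computes

From a 6 × 6 mm en-face angiogram `I(x, y) ∈ [0, 1]` of either plexus:

1. histogram equalization (empirical CDF over 256 bins);
2. multiscale Hessian ridge enhancement — Frangi response
   `V = exp(−R_b²/2β²) · (1 − exp(−S²/2γ²))` from the eigenvalues
   `|λ₁| ≤ |λ₂|` of the scale-normalized Hessian, zeroed where `λ₂ ≥ 0`,
   maximized over scales σ ∈ {1, 1.5, 2} px at a 1024² canonical grid;
3. a global threshold at the noise floor (the 95th percentile of the
   response over the background candidate set);
4. connected-component cleanup (8-connectivity, components < 10 px removed).

The binary mask `M` yields

* **MPD** (mean perfusion density) `= 100 · mean(M)` — percent of the field
  occupied by vessels;
* **MVD** (mean vascular density) `= L(skeleton(M)) / area` — skeletonized
  vessel length per unit area (mm/mm²), sensitive to individual capillary
  loss.

DCP images are first corrected for projection ("tail") artifacts by gated
subtraction of the SCP signal under the SCP vessel mask, with a robustly
fitted gain.

Since clinical acquisitions are not redistributable, `octa_density.synthetic`
generates vessel networks with known binary ground truth (branching random
walks with anastomosis, speckle, cyst-shaped avascular dropout, composited
projection tails) and case–control cohorts — 22 IRF ± SRF, 11 SRF and 11
healthy eyes — whose per-eye densities follow the published group means ± SD
per plexus, metric and timepoint (T0 = during exudation, T1 = after
resorption) and whose covariates follow the published prevalences. With
`recenter=True` each group's sample mean and SD are exact, so the regression
estimates below are reproduced to printed precision.

`octa_density.stats` supplies the inferential layer in a statsmodels-like
shape: `BaselineDensityModel` (univariable OLS screening at p < 0.1, then a
joint multivariable OLS with the fluid group always retained) and
`TimeEffectModel` (linear mixed model with a random intercept per eye and
age, fibrosis and atrophy as covariables, fitted by REML).

## Worked example

```python
from octa_density import (CohortSpec, generate_cohort,
                          BaselineDensityModel, TimeEffectModel)

cohort = generate_cohort(CohortSpec(seed=1))          # recentered by default
print(BaselineDensityModel(cohort, "scp_mpd").fit_univariable("group").summary())
print(TimeEffectModel(cohort, "scp_mpd", "IRF_SRF").fit().summary())
```

prints

```
Univariable OLS: scp_mpd ~ group   (n=44)
==============================================================
outcome factor           term estimate ci_low ci_high        p
scp_mpd  group group[IRF_SRF]    -7.00  -9.48   -4.52 1.18e-06
scp_mpd  group     group[SRF]    -2.20  -5.07    0.67    0.129
==============================================================
Mixed-model time effect on scp_mpd (IRF_SRF group, 22 eyes)
  T1 - T0 estimate : 2.70 (95% CI 1.16, 4.24)
  p-value          : 0.00151
  adjusted for     : age, fibrosis, atrophy
  random effects   : intercept per eye (REML)
```

During exudation, eyes with intraretinal fluid have an SCP perfusion density
7.0 percentage points below healthy eyes (the SRF-only deficit, −2.2, is not
significant); after fluid resorption the same eyes regain 2.7 points,
independently of age, fibrosis and atrophy.

The same workflow runs from the shell:

```bash
octa-density simulate --seed 1 --out cohort.csv
octa-density stats time-effect --cohort cohort.csv --group IRF_SRF --outcome scp_mpd
octa-density density --scp scp.png --dcp dcp.png --fov-mm 6.0 --out density.csv
octa-density run-all --seed 1 --out run/ --mode full_image_pipeline
```

`run-all` writes per-eye images, a cohort table, all regression tables and a
JSON manifest with content hashes; identical seeds give identical manifests.

## Limitations

The image chain is a reconstruction of a published processing recipe whose
proprietary implementation details are not public; absolute MVD values
depend on the skeleton length convention, and validation is against
synthetic networks, not clinical images. See `docs/methods.md`.
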