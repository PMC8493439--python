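# Methods

## WMH intensity model and segmentation

Brain-extracted FLAIR intensities inside the mask are modeled as a single
Gaussian; hyperintense (lesion) voxels are those strictly above
μ + z·σ with z = 2.1 by default. Two estimators of (μ, σ) are exposed:

* **moments** (default): in-mask sample mean and population SD (ddof 0).
  This is the estimator whose hand arithmetic the toy examples check
  (990 voxels at 100 and 10 at 200 give μ = 101, σ = √99).
* **trimmed**: symmetric removal of a fraction *f* (default 0.05) of the
  smallest and largest values, with the trimmed SD rescaled by the
  truncated-normal variance factor 1 − 2a·φ(a)/(1 − 2f), a = Φ⁻¹(1 − f), so
  that σ̂ estimates the full-distribution SD. Lesion voxels sit in the upper
  tail and inflate the moments σ; the trimmed variant is robust to that
  contamination. Which variant a historical in-house tool used is unknowable
  from its description, so both are provided and the choice is a parameter.

Ties exactly at the threshold are excluded (strict inequality). Connected
components (26-connectivity by default; 6/18 available) smaller than
`min_component_size` are removed. This automated size filter replaces
interactive manual editing of false positives, trading expert judgment for
reproducibility; an optional exclusion mask covers cases where specific
regions are known a priori to be artifactual. On the synthetic phantom the
largest pure-noise 26-connected component at the 2.1 SD threshold is
empirically ~12 voxels, so recovery experiments use a 20-voxel filter with
planted lesions of ~257 voxels (radius 4): well above noise, well below
lesions. Residual segmentation error then comes only from noise voxels
abutting a lesion surface, giving Dice ≥ 0.99.

Lobar volumes count labeled voxels per atlas code × voxel volume (from the
NIfTI header zooms), reported in cm³. The atlas is assumed grid-aligned
(identity transform); nonlinear coregistration is out of scope. Lobar
volumes plus the unassigned remainder sum to the total by construction.

## Symmetrized percent change

SPC = 100 · (T₂ − T₁) / (Δt · ½(T₁ + T₂)) %/year. Normalizing by the
two-timepoint average (rather than baseline) makes the measure exactly
antisymmetric under swapping timepoints, scale-invariant, and bounded by
200/Δt in magnitude; for small changes it agrees with the
baseline-normalized rate to second order. The simulator uses the closed
inverse T₂ = T₁(1 + s/2)/(1 − s/2), s = SPC·Δt/100, so thickness-derived
SPC reproduces the generating truth to machine precision.

## Vertexwise GLM and clusterwise inference

Per-vertex OLS of SPC on the focal WMH predictor plus covariates (age,
sex/gender, APOE ε4 carriage, baseline entorhinal thickness) is vectorized
across vertices from one factorization of XᵀX; t = β̂/SE with n − k residual
degrees of freedom (no smoothness correction of the dof). Rank-deficient
designs fail loudly, naming the collinear columns.

Cluster forming: vertices with |t| above the two-tailed critical value at
P < .01 are partitioned into edge-connected components separately for
positive and negative signs (opposite signs never merge). Extent is vertex
count by default; surface area (one third of incident face areas) optional.

Clusterwise p: the null distribution of the **maximum** cluster extent over
both signs is built from N synthetic null datasets and
p = (1 + #{null max ≥ observed extent}) / (N + 1), which cannot be zero.
Two null generators:

* **Freedman–Lane residual permutation** (default): refit on reduced-model
  fitted values plus row-permuted reduced-model residuals. This adapts
  automatically to the data's spatial covariance.
* **smooth-noise**: unit-variance Gaussian fields smoothed on the mesh,
  thresholded at the normal critical value; the smoothing level is
  estimated by inverting the residuals' mean edge-neighbor correlation
  against the smoothing operator's edge correlation.

A minimum of 100 iterations is enforced (tail stability). All Monte Carlo
is seeded; identical seeds give identical p values.

## Association models

All cohort-level models are OLS with classical t confidence intervals
(no robust SEs, as none are indicated for the original analyses).
Covariate sets are configuration, not code: `primary` (age, sex/gender,
APOE ε4, baseline entorhinal thickness), `primary-minus-entorhinal`, and
`primary-plus-education`; memory models additionally adjust for the
test-to-scan interval. Race/ethnicity is coded with non-Hispanic White as
reference and men as the sex reference. Standardized coefficients follow
β = b·SD(x)/SD(y) (variables are not jointly z-scored). WMH enters
untransformed in cm³. Group differences use analysis of covariance: an F
test of the two group indicators adjusted for age, sex/gender and APOE. No
multiplicity correction is applied across the secondary models, since none
is part of the analysis being reproduced.

## Synthetic data: what it emulates and what it does not

The FLAIR phantom is an ellipsoidal brain mask (≈90% of the grid) with
i.i.d. Gaussian background intensity, non-overlapping spherical lesions set
to exactly mean + offset·SD, and an axis-aligned quadrant partition into
frontal/temporal/parietal/occipital labels — chosen because every assignment
is trivially verifiable. It does not model MR physics, partial volume,
bias fields, or anatomical lesion distributions; passing recovery tests
shows the thresholding/filtering logic is correct, not that the threshold
generalizes to scanner data.

The cohort generator draws covariates from the study population's
descriptive marginals: age 73.16 (5.19) y; 60% women; White/Black/Hispanic
probabilities 0.317/0.373/0.310; APOE ε4 carriage 33.3%; education
12.80 (4.80) y (truncated at 0); baseline entorhinal thickness
3.30 (0.31) mm; scan interval 4.1 (2.4) y truncated to [0.5, 10] y (the
recruitment window bounds feasible follow-up). Total WMH is a log-normal
right-truncated at 40 cm³ and re-parameterized so the truncated distribution
has exactly mean 4.81 and SD 5.36 cm³ — truncation is needed because an
unbounded tail would occasionally demand a thinning rate beyond the
attainable 200/Δt bound, i.e. nonpositive follow-up thickness. Lobar volumes
are a Dirichlet split (concentration 20) of the total with expected shares
proportional to the lobar means 2.04/0.31/1.30/0.40 cm³ plus an extra-lobar
remainder, so lobar means match their targets while lobes remain positively
coupled to total burden.

True vertexwise SPC = intercept (−0.3 %/y) + global covariate effects +
planted WMH slopes (and group-specific extra slopes) inside designated
cluster vertex sets + spatially smooth residual noise (SD 1.0 %/y,
consistent with observed cluster-level SPC SDs of ~0.8–2). Smooth noise is
k iterations of neighbor-mean smoothing of i.i.d. vertex noise with rows of
the composite operator renormalized to unit variance per vertex; k = 2 by
default, because one iteration on the default 642-vertex icosphere
(~7 mm vertex spacing) already corresponds to roughly a 15 mm FWHM kernel.
The memory score is linear in true cluster-mean SPC (γ = 0.3, matching the
order of the observed recall–thinning slopes) and age, with residual SD 2 on
a selective-reminding-test-like scale. The mesh is an icosphere, not a
cortex: detection and calibration results demonstrate statistical
correctness of the machinery, not anatomical realism.

Calibration experiments plant the WMH slope at one residual SD of SPC per
cohort SD of the parietal WMH predictor (1.0/1.6 ≈ 0.625 %/y per cm³) — a
strong but not degenerate effect under which the clusterwise test should
and does detect the planted cluster in ≥ 80% of replicates at n = 300.

## Problem sizes

The family-wise error calibration runs 300 null datasets (n = 100 subjects,
642-vertex mesh) with 199 Monte Carlo iterations each; detection uses 25
replicates at n = 300; coefficient-recovery simulations use 200 replicates.
These sizes put the Monte Carlo bands (99% binomial band around the nominal
.05, ±5% mean bias, coverage in [.92, .98]) well within reach of a
single-CPU run while keeping each experiment a from-scratch recomputation.

## Numerical and degenerate-input conventions

Zero intensity variance, nonpositive thickness or interval, empty brain
mask, empty cluster averaging, impossible lesion placement, rank-deficient
designs, strata with constant WMH, and sub-100 Monte Carlo iteration counts
all raise explicit errors rather than degrading silently. Noiseless
(zero-residual) fits report SE = 0 and infinite t where the estimate is
nonzero. Pipeline outputs use uncompressed NIfTI and sorted-key JSON so
reruns are byte-identical; every stage seed derives from the single global
seed.

## Known limitations

No surface registration, >2 timepoints, mixed-effects longitudinal models,
random-field or TFCE correction, periventricular/deep WMH subdivision, or
bias-field handling. Clusterwise p values from the permutation variant are
not numerically comparable to historical smooth-noise simulation values on
real data. The generator's lesion contrast, spatial lesion distribution and
surface smoothness are conventions, not estimates from data.
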