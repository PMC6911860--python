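# Methods

`wmh_bullseye` quantifies white-matter hyperintensities (WMH) — the bright
lesions seen on T2-weighted MRI in conditions such as *GRN*-related
frontotemporal dementia and small-vessel disease — on synthetic phantoms
with exact ground truth. The package covers the full measurement chain:
image simulation, joint-contrast mixture segmentation with a longitudinal
constraint, bullseye (lobe × depth-layer) white-matter parcellation, and the
downstream log-volume statistics. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Phantom model

A subject is a set of concentric ellipsoids on a regular grid (default 64³,
1 mm isotropic): background, a central CSF "ventricle"
(normalized radius ρ ≤ 0.18), a white-matter shell (0.18 < ρ ≤ 0.85) and a
grey-matter rim (0.85 < ρ ≤ 1). The head semi-axes are 0.45 of the grid
extent, mildly anisotropic so no axis is privileged. Lobes are
dominant-axis angular sectors around the ventricle centroid (+y frontal,
−y occipital, +z parietal, remainder temporal); a peri-ventricular band
(ρ ≤ 0.30) is labelled subcortical and kept out of the four lobes.
Ellipsoids rather than template anatomy were chosen deliberately: every
label has an analytic definition, so the parcellation and volumetry layers
can be tested against exact oracles.

Lesions are spheres planted wholly inside WM (centre at least one radius
from the WM boundary, non-overlapping, bounded retries then an explicit
error). The centre's normalized ventricle-to-cortex depth d is drawn from a
density ∝ (1−d)^k with k = 5·`periventricular_bias`; bias 1 concentrates
lesions periventricularly (the distribution these lesions show in practice),
bias 0 is uniform.

Intensities are tissue means (T1/T2: CSF 30/100, GM 70/60, WM 100/45,
arbitrary units) plus lesion offsets (T1 −20, T2 +10 by default) plus
i.i.d. Gaussian noise of SD `noise_sd` (default 2). `tissue_sds` are the
*nominal* class SDs — the scale on which "a k-SD lesion" and the z-score
thresholds are expressed — and default to the noise SD; they do not add
noise themselves, so a `noise_sd = 0` phantom is exactly piecewise
constant. Additive Gaussian rather than Rician noise is used: the
segmentation model is Gaussian and at the simulated SNR the distinction is
immaterial. No bias field, cortical folding or scanner harmonization is
simulated.

Longitudinal series fix the geometry and lesion centres (drawn once), grow
the radii by `growth_per_visit` mm per visit, resample each visit under its
rigid offset (trilinear for intensities, nearest for labels) and add
independent per-visit noise.

### Cohort simulator

Log lesion volume follows a two-level linear mixed model
`y_ij = μ + γ_g + b0_i + (α_g + b1_i)·t_ij + ε_ij` with subject random
intercept (SD 0.55) and slope (SD 0.03), residual SD 0.12. Default group
effects are the multiplicative excesses and annual accruals the analysis
stack is meant to recover (presymptomatic +17.8%, symptomatic +48.2%;
accrual 4.32/1.68/9.16 %/year). Covariates (group sizes 203/101/32, age,
sex ratios, education, scanner mix, TIV, plasma NfL/GFAP as moment-matched
lognormals, TMEM106B genotype frequencies, cognitive z-scores) reproduce the
published cohort structure of familial-FTD studies so the model code sees
realistic columns. `cognition_loading` ties cognitive scores to the
subject's lesion-load deviation, giving a planted brain–behaviour
association for the residual-correlation tests. A single baseline SD is
used for the subject intercept (the "baseline SD" and "random intercept SD"
describe the same dispersion). The table contains no missingness, no
scanner-specific intensity effects and no genuinely nonlinear trajectories —
passing tests show estimator correctness, not robustness to those
real-data features.

## Intensity mixture

Voxel intensity pairs (T1, T2) inside the brain mask are modelled as a
bivariate Gaussian mixture: one or more inlier components per tissue (CSF,
GM, WM) plus 1–3 unconstrained outlier components for unexpected signal.
Spatial tissue priors A_c(v) (atlas-style probability maps; here the
phantom's labels) enter as fixed per-class spatial factors: component k of
class c contributes w_k·A_c(v)·N(x_v; μ_k, Σ_k), with the global weights
w_k learned. Treating the voxel location as an observed variable with
class-conditional density ∝ A_c makes the EM below *exact* for this
objective — the log-likelihood trace is monotone, which the tests assert —
while still letting the outlier class weight adapt (a 5% planted uniform
contamination is recovered as 0.05 ± 0.02). The outlier class has a flat
spatial factor. How spatial priors couple to the mixture was an open design
point; this coupling was chosen for its exactness.

Implementation details: seeded k-means initialization on a 10% subsample
(outlier components seeded from the high-T2 tail with inflated covariance);
covariance regularization ε = 1e-6 × mean data variance, escalated only if a
Cholesky factorization still fails; convergence at relative log-likelihood
change < 1e-5 or 200 iterations; constant images raise a
`DegenerateInputError` rather than fitting.

The number of components is selected by exhaustive search over
K_tissue ∈ {1, 2} (shared across tissues) × K_outlier ∈ {1, 2, 3}, scored by
`log-likelihood − ½·p·log n` (BIC form, p = 5 per component plus K−1
weights; higher is better). Exhaustive search replaces incremental
split/merge schemes: at these problem sizes it selects the same models and
is far easier to verify.

## Lesion extraction

A voxel is a WMH candidate iff (a) its outlier posterior exceeds `p_min`
(0.5), (b) its T2 intensity exceeds the moment-pooled WM inlier mean by at
least `z_min` WM SDs — hyperintense side only, so hypointense outliers are
never selected, (c) the WM prior dominates the other tissues *and* holds at
least `wm_prior_min` (0.9) of the total prior mass, and (d) it survives
removal of the 1-voxel (face-connected) dilation of the ventricle mask.
The prior-confidence floor in (c) matters when priors have been resampled:
partial-volume voxels on the WM/GM boundary mimic lesion intensity on both
contrasts and would otherwise leak in.

Candidates are grouped by 26-connectivity; a component is a lesion iff it
has ≥ `min_size` (5) voxels, ≥ `f_min` (50%) of them in confident WM, and
mean T2 z-score ≥ `z_comp`; everything else is recorded as an artefact in
the component table. Defaults `z_min = 2.0`, `z_comp = 2.5`: a voxelwise
z ≥ 3 rule would discard half the voxels of a 3-SD lesion by construction
and caps the achievable overlap, whereas a 2-SD margin keeps false positives
controlled through the posterior and component rules. All thresholds are
config fields.

Detected lesions are inpainted on T1 by drawing from a Gaussian fitted to
the normal-appearing WM in a 3-voxel dilation shell around each component
(global WM statistics as a warned fallback), seeded for reproducibility.
The two-pass procedure re-fits the tissue model on the filled T1 so that
T1-hypointense lesions no longer bias the GM/WM maps; tissue labels are the
argmax over inlier-class posteriors.

## Longitudinal constraint

Visits are co-registered groupwise: a translations-only pass, then full
rigid passes (Nelder-Mead on mean squared error, half-voxel initial
simplex), each visit linearly intensity-rescaled to the evolving average
(least-squares gain, mean gain normalized to 1), transforms de-meaned so the
average space does not drift, iterated until the mean transform update is
below 0.01 voxel; a cost rising three consecutive iterations raises a
divergence error. Registration is restricted to rigid because the phantoms
are rigid; transforms below 0.05 voxel/degree are treated as exact identity
so that resampling noise is not injected into perfectly aligned series.

The mixture (including the selected component counts) is fitted once on the
average image. Each visit is then re-fit with MAP tethering: every M-step
blends the visit statistics with the average-image component (pseudo-count
`tether_strength · n/K`, default strength 1.0 — equal weight), and the
candidate z-score statistics are taken from the average-image model so all
visits share one operating point. Lesion masks are produced in native visit
space (priors and masks mapped through the inverse transforms); a 1-visit
series falls back to the cross-sectional path. The tethering mechanism and
the native-space choice were open design points. Under inter-visit motion,
interpolation partial volume at lesion edges inflates measured volumes by
roughly 10–20%; the growth *ordering* is preserved.

## Bullseye parcellation

Each WM voxel takes the lobe of its nearest cortical (GM) voxel — one
Euclidean distance transform per lobe, in mm, ties broken in the fixed
order frontal, parietal, occipital, temporal; subcortical WM keeps its own
label and joins no lobe (and subcortical lesion load is reported separately,
inside the total but outside the four lobes). Normalized depth is
d = d_v/(d_v + d_c) with d_v, d_c the Euclidean distances to the
ventricular and cortical surfaces (0 on the ventricle, 1 at cortex; an
overlap of the two surfaces inside WM is an error). Depth quartiles give
four equidistant layers whose middle two are merged: periventricular
[0, 0.25), medial [0.25, 0.75), peripheral [0.75, 1], boundary depths going
to the outer bin. Euclidean rather than geodesic distance is used because
it admits an exact brute-force oracle and is adequate on convex phantoms;
geodesic depth is a possible extension for folded anatomy.

Regional volumes (total, per lobe, per layer, per lobe×layer cell, per
hemisphere, for both WMH and GM) are voxel counts × voxel volume, so the
conservation identities (lobes, layers and hemispheres each summing to the
total) hold exactly and are property-tested. The asymmetry index is
(L−R)/(L+R), undefined (error) when both hemispheres are empty. Tract
involvement is ranked by the number of lesion voxels with tract probability
above 0.25, ties alphabetical; a synthetic 3-tract atlas stands in for a
tractography atlas.

## Statistics

Volumes are log-transformed with an offset of one voxel volume so the
transform exists at zero load. Cross-sectional models are OLS on the
latest-visit log volume with age, sex, scanner and TIV as covariates
(treatment coding, most frequent level as reference); log-scale coefficients
are reported as percent excess 100·(exp β − 1) with transformed 95% CIs, and
a Shapiro–Wilk statistic on the residuals is attached. Rank-deficient
designs raise an error naming the collinear columns.

Longitudinal accrual uses a two-level linear mixed model (statsmodels
MixedLM, REML, unstructured 2×2 random-effects covariance) with random
intercept and random slope on time and fixed group×time interactions; the
group accrual in %/year is the percent-excess transform of its total time
slope. Baseline age is used as the age covariate because within-subject
ageing is exactly collinear with time. Rows are sorted canonically before
fitting so estimates do not depend on table order. Calibration at reduced
size (15+15 subjects × 3 visits, 1000 replicates) puts the null group×time
rejection rate at ~4–6%.

Brain–behaviour association is the Spearman correlation between residuals:
log volume residualized on age/sex/scanner/TIV, the cognitive score on
age/sex/education (≥5 complete cases required; constant scores are an
error). Severity stratification uses fixed thresholds of 1000 and 2500 mm³
— 0.07% and 0.18% of a 1400 ml mean TIV. Reported percentages are rounded
half-up (1 decimal for proportions, 2 for occupancies). No
multiple-comparison correction is applied anywhere, by design (the
dependent regional outcomes are strongly correlated); `adjust_pvalues`
offers an explicit opt-in (Bonferroni, Holm, FDR).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 64³ phantoms for
cross-sectional segmentation, 48³ for the 10-seed longitudinal comparison
(at 3-SD lesion contrast, where per-visit measurement noise is actually
present — at 5 SD both pipelines saturate), 32³ grids for the brute-force
parcellation oracle, 100×4 subject-visits for accrual recovery and 1000
reduced-size replicates for null calibration. Seeds are explicit
everywhere; identical seeds give bit-identical phantoms and pipelines.

## Known limitations

Convex geometry only (no folding, so Euclidean ≈ geodesic by
construction); two contrasts, no FLAIR; no perivascular-space
disambiguation; no deformable registration; no bias field or Rician noise;
the phantom's lesion contrast parameters are free knobs, not calibrated to
any acquisition. Statistical results on the simulated cohort demonstrate
estimator behaviour under the generator's assumptions, not under real
cohort idiosyncrasies (scanner drift, informative dropout, skewed visit
schedules).
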