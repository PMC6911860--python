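# wmh-bullseye

Quantification of white-matter hyperintensities (WMH) — the T2-bright
lesions of small-vessel disease and *GRN*-related frontotemporal dementia —
as a fully testable pipeline on synthetic brain phantoms with exact ground
truth. The package is aimed at methods developers who want every stage of a
lesion-burden study (segmentation → regional localization → statistics)
exercised against known answers.

It provides, as a Python library plus a thin CLI:

- **Phantom simulation** — seeded T1/T2 volume pairs (concentric-ellipsoid
  head, spherical WM lesions with periventricular placement bias),
  longitudinal series with lesion growth under rigid motion, and cohort
  covariate tables drawn from a linear mixed model with planted group
  effects.
- **Lesion segmentation** — the joint T1/T2 intensity distribution is
  modelled as a Gaussian mixture with per-tissue *inlier* components and
  unconstrained *outlier* components, component counts chosen by BIC
  (`LL − ½·p·log n`). Candidate WMH voxels come from the outlier posterior
  under hyperintensity (T2 z-score vs normal-appearing WM) and WM-location
  constraints, with a 1-voxel exclusion border around the ventricles;
  connected components are classified lesion/artefact; detected lesions are
  inpainted on T1 and the tissue model re-fitted (two-pass GM correction).
- **Longitudinal constraint** — visits are rigidly co-registered to a
  within-subject average image (groupwise, translations first, then full
  rigid, with intensity gain matching); the mixture fitted on the average
  anchors each visit's segmentation, reducing between-visit measurement
  noise.
- **Bullseye parcellation** — WM subdivided by nearest cortical lobe
  (distance transform; subcortical kept separate) and by normalized
  ventricle-to-cortex depth d = d_v/(d_v+d_c) cut into periventricular
  [0, 0.25), medial [0.25, 0.75) and peripheral [0.75, 1] layers; regional
  WMH/GM volumes with exact conservation identities, the asymmetry index
  (L−R)/(L+R), and tract-overlap ranking.
- **Statistics** — log-volume transform with a 1-voxel offset,
  covariate-adjusted OLS reported as percent excess 100·(exp β − 1),
  two-level mixed models (random intercept + slope, REML) for annual
  accrual, residual Spearman correlations with cognition, severity
  stratification at 1000/2500 mm³ (0.07%/0.18% of a 1400 ml TIV), and
  cohort summary tables.

## Worked example

```python
from wmh_bullseye import (PhantomSpec, SegmentationConfig, generate_phantom,
                          two_pass_segmentation)

spec = PhantomSpec(rng_seed=11)                  # 64³, 3 lesions, 5-SD contrast
t1, t2, truth = generate_phantom(spec)
lesions, tissue, _ = two_pass_segmentation(
    t1, t2, truth.tissue_priors(), truth.brain_mask,
    truth.ventricle_mask, spec.voxel_volume_mm3, SegmentationConfig())
print(lesions.volume_mm3, truth.lesion_volume_mm3())
```

Running `python examples/02_segment_lesions.py` (which adds the Dice score
and component table) prints:

```
selected 4 components (outlier weight 0.0050)
measured lesion volume 232 mm3 (truth 237 mm3), Dice 0.989
 component  size_voxels  mean_t2_z verdict
         1          171   4.976906  lesion
         2           33   5.084505  lesion
         3           28   5.212534  lesion
GM voxels: pass-1 32180, after inpainting 31949, truth 31944
```

Reading: the BIC search kept one Gaussian per tissue plus one outlier
component carrying 0.5% of the voxels; the three planted spheres were
recovered at Dice 0.989 with mean T2 z-scores ≈ 5 (the planted contrast);
inpainting the T1-hypointense lesions moved the grey-matter count from 236
voxels above truth to 5.

The other scripts in `examples/` walk through phantom bookkeeping,
bullseye regional tables, longitudinal series and the cohort statistics,
each printing what its numbers mean.

A pipeline run from the shell:

```bash
wmh-bullseye run --out run1 --seed 3     # simulate → segment → parcellate → analyse
wmh-bullseye simulate --out demo --seed 1 --grid 48
wmh-bullseye analyse --table run1/cohort.csv --model long --outcome log_wmh
```

Every run writes a `manifest.json` with SHA-256 hashes of all outputs;
rerunning with the same seed reproduces them byte for byte.

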