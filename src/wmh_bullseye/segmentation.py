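"""From outlier posteriors to a lesion mask.

Candidate voxels are taken from the mixture's outlier class under intensity
(T2-hyperintense relative to normal-appearing WM) and location (WM-dominant
prior) constraints, a 1-voxel border around the ventricles is excluded,
connected components are classified as lesion or artefact by size, WM-interior
fraction and mean T2 z-score, detected lesions are inpainted on T1 with
locally sampled normal-appearing WM, and a second tissue fit on the filled
T1 yields corrected GM/WM maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .mixture import (MixtureConfig, MixtureModel, ResponsibilityMap,
                      fit_mixture)

TISSUE_CODES = {"csf": 1, "gm": 2, "wm": 3}


def _structure(connectivity: int):
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndi.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndi.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class SegmentationConfig:
    p_min: float = 0.5            # outlier posterior threshold
    z_min: float = 2.0            # voxelwise T2 z-score vs WM inliers
    min_size: int = 5             # voxels
    f_min: float = 0.5            # WM-interior fraction per component
    z_comp: float = 2.5           # mean component T2 z-score
    wm_prior_min: float = 0.9     # WM-prior confidence floor for candidates
    connectivity: int = 26        # component labelling
    border_connectivity: int = 6  # ventricular border dilation
    inpaint_dilation: int = 3     # shell radius (voxels) for local WM stats
    seed: int = 0
    mixture: MixtureConfig = field(default_factory=MixtureConfig)


@dataclass
class CandidateMap:
    mask: np.ndarray
    passed_intensity: np.ndarray
    passed_location: np.ndarray


@dataclass
class LesionMask:
    mask: np.ndarray
    voxel_volume_mm3: float
    component_table: pd.DataFrame

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_mm3


def exclude_ventricular_border(candidates: CandidateMap | np.ndarray,
                               ventricle_mask: np.ndarray,
                               connectivity: int = 6):
    """Drop candidates inside the 1-voxel dilation of the ventricles."""
    cand = candidates.mask if isinstance(candidates, CandidateMap) else \
        np.asarray(candidates, bool)
    ventricle_mask = np.asarray(ventricle_mask, bool)
    if cand.shape != ventricle_mask.shape:
        raise ValueError("candidate and ventricle grids differ")
    if not ventricle_mask.any():
        warnings.warn("empty ventricle mask: border exclusion skipped")
        return candidates
    border = ndi.binary_dilation(ventricle_mask,
                                 structure=_structure(connectivity))
    kept = cand & ~border
    if isinstance(candidates, CandidateMap):
        return CandidateMap(kept, candidates.passed_intensity,
                            candidates.passed_location)
    return kept


def _t2_zscore(resp: ResponsibilityMap, model: MixtureModel):
    wm_mean, wm_sd = model.class_stats("wm")
    z = np.zeros(resp.mask.shape)
    z[resp.mask] = (resp.data[:, 1] - wm_mean[1]) / wm_sd[1]
    return z


def select_candidates(resp: ResponsibilityMap, model: MixtureModel,
                      tissue_priors: dict, ventricle_mask: np.ndarray,
                      config: SegmentationConfig | None = None
                      ) -> CandidateMap:
    """Outlier voxels that are T2-hyperintense and sit in WM-dominant space."""
    config = config or SegmentationConfig()
    if not model.class_components("wm"):
        raise ValueError("model has no WM inlier component")
    p_out = resp.class_posterior("outlier")
    z = _t2_zscore(resp, model)
    passed_intensity = (p_out > config.p_min) & (z >= config.z_min)
    stack = np.stack([np.asarray(tissue_priors[k], float)
                      for k in ("csf", "gm", "wm")])
    # WM must dominate AND be confident: fractional priors (e.g. after
    # resampling) near the cortical sheet are excluded, since tissue
    # partial-volume there mimics lesion intensity on both contrasts
    total = stack.sum(axis=0)
    wm_frac = np.divide(stack[2], total, out=np.zeros_like(total),
                        where=total > 0)
    wm_dominant = (stack.argmax(axis=0) == 2) \
        & (wm_frac >= config.wm_prior_min)
    passed_location = wm_dominant & resp.mask
    cand = CandidateMap(passed_intensity & passed_location,
                        passed_intensity, passed_location)
    return exclude_ventricular_border(cand, ventricle_mask,
                                      config.border_connectivity)


def classify_components(candidates: CandidateMap, t2, model: MixtureModel,
                        wm_mask: np.ndarray, voxel_volume_mm3: float = 1.0,
                        config: SegmentationConfig | None = None
                        ) -> LesionMask:
    """Label connected candidates, keep lesion-like components.

    A component is a lesion iff it has at least ``min_size`` voxels, at least
    ``f_min`` of them inside WM, and mean T2 z-score at least ``z_comp``;
    everything else is recorded as an artefact.
    """
    config = config or SegmentationConfig()
    cand = candidates.mask
    labels, n = ndi.label(cand, structure=_structure(config.connectivity))
    wm_mean, wm_sd = model.class_stats("wm")
    t2 = np.asarray(t2, float)
    rows = []
    keep = np.zeros_like(cand)
    for cid in range(1, n + 1):
        sel = labels == cid
        size = int(sel.sum())
        zbar = float((t2[sel].mean() - wm_mean[1]) / wm_sd[1])
        f_wm = float((sel & np.asarray(wm_mask, bool)).sum() / size)
        verdict = ("lesion" if size >= config.min_size
                   and f_wm >= config.f_min and zbar >= config.z_comp
                   else "artefact")
        if verdict == "lesion":
            keep |= sel
        centroid = tuple(float(c) for c in ndi.center_of_mass(sel))
        rows.append({"component": cid, "size_voxels": size,
                     "centroid_i": centroid[0], "centroid_j": centroid[1],
                     "centroid_k": centroid[2], "mean_t2_z": zbar,
                     "wm_fraction": f_wm, "verdict": verdict})
    table = pd.DataFrame(rows, columns=["component", "size_voxels",
                                        "centroid_i", "centroid_j",
                                        "centroid_k", "mean_t2_z",
                                        "wm_fraction", "verdict"])
    return LesionMask(keep, float(voxel_volume_mm3), table)


def inpaint_lesions(t1, lesion_mask, wm_mask,
                    config: SegmentationConfig | None = None) -> np.ndarray:
    """Replace lesion T1 intensities with local normal-appearing WM draws.

    Statistics come from a dilated shell around each lesion component
    (lesions excluded); if a shell holds no WM voxel, global WM statistics
    are used with a warning.  Non-lesion voxels are untouched.
    """
    config = config or SegmentationConfig()
    t1 = np.asarray(t1, float).copy()
    lesion = np.asarray(lesion_mask, bool)
    wm = np.asarray(wm_mask, bool)
    if not lesion.any():
        return t1
    rng = np.random.default_rng(config.seed)
    labels, n = ndi.label(lesion, structure=_structure(config.connectivity))
    normal_wm = wm & ~lesion
    for cid in range(1, n + 1):
        sel = labels == cid
        shell = ndi.binary_dilation(
            sel, structure=_structure(config.connectivity),
            iterations=config.inpaint_dilation) & normal_wm
        if not shell.any():
            warnings.warn("inpainting shell holds no WM; using global "
                          "WM statistics")
            shell = normal_wm
            if not shell.any():
                raise ValueError("no normal-appearing WM to sample from")
        mu = float(t1[shell].mean())
        sd = float(t1[shell].std())
        t1[sel] = rng.normal(mu, sd, int(sel.sum()))
    return t1


def segment_cross_sectional(t1, t2, tissue_priors, brain_mask,
                            ventricle_mask, voxel_volume_mm3: float = 1.0,
                            config: SegmentationConfig | None = None):
    """Single-visit pipeline: fit mixture → candidates → components."""
    config = config or SegmentationConfig()
    model, resp = fit_mixture(t1, t2, tissue_priors, brain_mask,
                              config.mixture)
    cand = select_candidates(resp, model, tissue_priors, ventricle_mask,
                             config)
    wm_dominant = np.stack([np.asarray(tissue_priors[k], float)
                            for k in ("csf", "gm", "wm")]).argmax(axis=0) == 2
    lesions = classify_components(cand, t2, model, wm_dominant,
                                  voxel_volume_mm3, config)
    return lesions, model, resp


def two_pass_segmentation(t1, t2, tissue_priors, brain_mask, ventricle_mask,
                          voxel_volume_mm3: float = 1.0,
                          config: SegmentationConfig | None = None):
    """Lesion segmentation followed by inpainting and tissue re-estimation.

    Pass 1 fits the mixture on the native pair and extracts lesions; the T1
    is then filled with normal-appearing WM at lesion locations, and pass 2
    re-fits the tissue model on the corrected T1 to produce the final
    tissue maps.  Returns ``(lesions, tissue_labels, posteriors)`` where
    ``tissue_labels`` uses codes 1=CSF, 2=GM, 3=WM.
    """
    config = config or SegmentationConfig()
    lesions, model, resp = segment_cross_sectional(
        t1, t2, tissue_priors, brain_mask, ventricle_mask,
        voxel_volume_mm3, config)
    wm_dominant = np.stack([np.asarray(tissue_priors[k], float)
                            for k in ("csf", "gm", "wm")]).argmax(axis=0) == 2
    t1_filled = inpaint_lesions(t1, lesions.mask, wm_dominant, config)
    model2, resp2 = fit_mixture(t1_filled, t2, tissue_priors, brain_mask,
                                config.mixture)
    tissue_labels = resp2.hard_tissue_labels(TISSUE_CODES)
    posteriors = {k: resp2.class_posterior(k) for k in TISSUE_CODES}
    return lesions, tissue_labels, posteriors


def pass1_tissue_labels(resp: ResponsibilityMap) -> np.ndarray:
    """Tissue labels from an uncorrected (pass-1) fit, for comparison."""
    return resp.hard_tissue_labels(TISSUE_CODES)
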