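"""Lesion extraction: border exclusion, candidate rules, component
classification, inpainting and the two-pass tissue correction."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from wmh_bullseye import (MixtureConfig, SegmentationConfig,
                          classify_components, exclude_ventricular_border,
                          fit_mixture, inpaint_lesions,
                          segment_cross_sectional, select_candidates,
                          two_pass_segmentation)
from wmh_bullseye.phantom import GM, WM, PhantomSpec, generate_phantom
from wmh_bullseye.segmentation import CandidateMap, pass1_tissue_labels


def dice(a, b):
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2 * (a & b).sum() / max(a.sum() + b.sum(), 1)


class TestVentricularBorder:
    def test_face_adjacent_candidate_removed(self):
        vent = np.zeros((9, 9, 9), bool)
        vent[4, 4, 4] = True
        cand = np.zeros((9, 9, 9), bool)
        cand[5, 4, 4] = True          # face neighbour
        assert not exclude_ventricular_border(cand, vent).any()

    def test_distant_candidate_retained(self):
        vent = np.zeros((9, 9, 9), bool)
        vent[4, 4, 4] = True
        cand = np.zeros((9, 9, 9), bool)
        cand[7, 4, 4] = True          # 3 voxels away
        assert exclude_ventricular_border(cand, vent).sum() == 1

    def test_removed_count_matches_brute_force_shell(self, rng):
        vent = np.zeros((16, 16, 16), bool)
        vent[6:10, 6:10, 6:10] = True
        cand = np.ones((16, 16, 16), bool)
        kept = exclude_ventricular_border(cand, vent)
        # brute force: voxels with Chebyshev-1 face neighbour in ventricle
        shell = np.zeros_like(vent)
        idx = np.argwhere(vent)
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                  (0, 0, 1), (0, 0, -1), (0, 0, 0)):
            shell[tuple((idx + d).T)] = True
        assert (cand.sum() - kept.sum()) == shell.sum()

    def test_empty_ventricle_mask_warns_and_passes_through(self):
        cand = np.ones((5, 5, 5), bool)
        with pytest.warns(UserWarning):
            out = exclude_ventricular_border(cand, np.zeros((5, 5, 5), bool))
        assert np.array_equal(out, cand)


@pytest.fixture(scope="module")
def fitted_phantom():
    spec = PhantomSpec(rng_seed=11)
    t1, t2, truth = generate_phantom(spec)
    cfg = SegmentationConfig(mixture=MixtureConfig(fixed_k=(1, 2), seed=0))
    model, resp = fit_mixture(t1, t2, truth.tissue_priors(),
                              truth.brain_mask, cfg.mixture)
    return spec, t1, t2, truth, cfg, model, resp


class TestSelectCandidates:
    def test_planted_lesions_selected(self, fitted_phantom):
        spec, t1, t2, truth, cfg, model, resp = fitted_phantom
        cand = select_candidates(resp, model, truth.tissue_priors(),
                                 truth.ventricle_mask, cfg)
        core = truth.lesion_mask & ~ndi.binary_dilation(
            truth.ventricle_mask)
        assert (cand.mask & core).sum() / core.sum() >= 0.9

    def test_hypointense_outliers_never_selected(self):
        spec = PhantomSpec(rng_seed=13, lesion_t2_offset=-12.0,
                           lesion_t1_offset=0.0)
        t1, t2, truth = generate_phantom(spec)
        cfg = SegmentationConfig(mixture=MixtureConfig(fixed_k=(1, 2),
                                                       seed=0))
        model, resp = fit_mixture(t1, t2, truth.tissue_priors(),
                                  truth.brain_mask, cfg.mixture)
        cand = select_candidates(resp, model, truth.tissue_priors(),
                                 truth.ventricle_mask, cfg)
        assert not (cand.mask & truth.lesion_mask).any()

    def test_gm_located_hyperintensity_rejected(self, fitted_phantom):
        spec, t1, t2, truth, cfg, model, resp = fitted_phantom
        cand = select_candidates(resp, model, truth.tissue_priors(),
                                 truth.ventricle_mask, cfg)
        assert not (cand.mask & truth.gm_mask).any()

    def test_no_wm_component_errors(self, fitted_phantom):
        from wmh_bullseye import GaussianComponent, MixtureModel
        spec, t1, t2, truth, cfg, model, resp = fitted_phantom
        bad = MixtureModel([GaussianComponent(np.zeros(2), np.eye(2), 1.0,
                                              "gm")], log_likelihood=-1.0)
        with pytest.raises(ValueError):
            select_candidates(resp, bad, truth.tissue_priors(),
                              truth.ventricle_mask, cfg)


class TestClassifyComponents:
    def test_tiny_component_is_artefact(self, fitted_phantom):
        spec, t1, t2, truth, cfg, model, resp = fitted_phantom
        cand = np.zeros(spec.grid_shape, bool)
        cand[30, 30, 30] = True
        lm = classify_components(CandidateMap(cand, cand, cand), t2, model,
                                 truth.wm_mask, 1.0, cfg)
        assert lm.component_table.verdict.iloc[0] == "artefact"
        assert not lm.mask.any()

    def test_planted_sphere_detected_with_high_dice(self, fitted_phantom):
        spec, t1, t2, truth, cfg, model, resp = fitted_phantom
        cand = select_candidates(resp, model, truth.tissue_priors(),
                                 truth.ventricle_mask, cfg)
        lm = classify_components(cand, t2, model, truth.wm_mask, 1.0, cfg)
        assert dice(lm.mask, truth.lesion_mask) >= 0.9

    def test_component_outside_wm_is_artefact(self, fitted_phantom):
        spec, t1, t2, truth, cfg, model, resp = fitted_phantom
        # bright rim: 20 voxels, 80% placed in GM
        cand = np.zeros(spec.grid_shape, bool)
        gm_idx = np.argwhere(truth.gm_mask)[:16]
        wm_idx = np.argwhere(truth.wm_mask)[:4]
        cand[tuple(gm_idx.T)] = True
        cand[tuple(wm_idx.T)] = True
        lm = classify_components(CandidateMap(cand, cand, cand),
                                 t2 + 20.0, model, truth.wm_mask, 1.0, cfg)
        assert (lm.component_table.verdict == "artefact").all()

    def test_volume_bookkeeping(self, fitted_phantom):
        spec, t1, t2, truth, cfg, model, resp = fitted_phantom
        cand = select_candidates(resp, model, truth.tissue_priors(),
                                 truth.ventricle_mask, cfg)
        lm = classify_components(cand, t2, model, truth.wm_mask, 2.0, cfg)
        lesion_rows = lm.component_table[lm.component_table.verdict
                                         == "lesion"]
        assert lm.volume_mm3 == pytest.approx(
            lesion_rows.size_voxels.sum() * 2.0)


class TestInpainting:
    def test_empty_mask_is_identity(self, fitted_phantom):
        spec, t1, t2, truth, cfg, *_ = fitted_phantom
        out = inpaint_lesions(t1, np.zeros_like(truth.lesion_mask),
                              truth.wm_mask, cfg)
        assert np.array_equal(out, t1)

    def test_filled_matches_local_wm_statistics(self, fitted_phantom):
        spec, t1, t2, truth, cfg, *_ = fitted_phantom
        out = inpaint_lesions(t1, truth.lesion_mask, truth.wm_mask, cfg)
        labels, n = ndi.label(truth.lesion_mask)
        for cid in range(1, n + 1):
            sel = labels == cid
            shell = ndi.binary_dilation(sel, iterations=3) \
                & truth.wm_mask & ~truth.lesion_mask
            assert abs(out[sel].mean() - t1[shell].mean()) \
                <= 0.5 * t1[shell].std()

    def test_untouched_outside_mask(self, fitted_phantom):
        spec, t1, t2, truth, cfg, *_ = fitted_phantom
        out = inpaint_lesions(t1, truth.lesion_mask, truth.wm_mask, cfg)
        outside = ~truth.lesion_mask
        assert np.array_equal(out[outside], t1[outside])

    def test_global_fallback_warns(self):
        t1 = np.full((8, 8, 8), 100.0)
        lesion = np.zeros((8, 8, 8), bool)
        lesion[2:6, 2:6, 2:6] = True
        wm = np.zeros((8, 8, 8), bool)
        wm[0, 0, 0] = True   # WM exists but far outside every shell
        t1[0, 0, 0] = 90.0
        with pytest.warns(UserWarning):
            out = inpaint_lesions(t1, lesion, wm,
                                  SegmentationConfig(inpaint_dilation=1))
        assert np.isfinite(out).all()


class TestTwoPass:
    def test_inpainting_improves_gm_volume(self):
        # strongly T1-hypointense lesions bias pass-1 GM upward
        spec = PhantomSpec(rng_seed=21, lesion_count=3,
                           lesion_radius_range=(2.5, 3.5),
                           lesion_t1_offset=25.0)
        t1, t2, truth = generate_phantom(spec)
        cfg = SegmentationConfig(mixture=MixtureConfig(fixed_k=(1, 2),
                                                       seed=0))
        model, resp = fit_mixture(t1, t2, truth.tissue_priors(),
                                  truth.brain_mask, cfg.mixture)
        gm1 = (pass1_tissue_labels(resp) == GM).sum()
        _, tissue2, _ = two_pass_segmentation(
            t1, t2, truth.tissue_priors(), truth.brain_mask,
            truth.ventricle_mask, 1.0, cfg)
        gm2 = (tissue2 == GM).sum()
        gm_true = truth.gm_mask.sum()
        assert abs(gm2 - gm_true) <= abs(gm1 - gm_true)

    def test_lesion_free_phantom_passes_agree(self):
        spec = PhantomSpec(rng_seed=22, lesion_count=0)
        t1, t2, truth = generate_phantom(spec)
        cfg = SegmentationConfig(mixture=MixtureConfig(fixed_k=(1, 1),
                                                       seed=0))
        model, resp = fit_mixture(t1, t2, truth.tissue_priors(),
                                  truth.brain_mask, cfg.mixture)
        pass1 = pass1_tissue_labels(resp)
        lesions, pass2, _ = two_pass_segmentation(
            t1, t2, truth.tissue_priors(), truth.brain_mask,
            truth.ventricle_mask, 1.0, cfg)
        brain = truth.brain_mask
        assert (pass1[brain] != pass2[brain]).mean() <= 0.01
        assert lesions.volume_mm3 == 0.0

    def test_mask_volume_equals_component_sum(self, fitted_phantom):
        spec, t1, t2, truth, cfg, *_ = fitted_phantom
        lesions, _, _ = two_pass_segmentation(
            t1, t2, truth.tissue_priors(), truth.brain_mask,
            truth.ventricle_mask, spec.voxel_volume_mm3, cfg)
        lesion_rows = lesions.component_table[
            lesions.component_table.verdict == "lesion"]
        assert lesions.mask.sum() == lesion_rows.size_voxels.sum()


class TestEndToEndContrast:
    def test_dice_thresholds_by_contrast(self):
        # 5-SD contrast: Dice >= 0.9; 3-SD: Dice >= 0.8
        for offset, target in ((10.0, 0.9), (6.0, 0.8)):
            spec = PhantomSpec(rng_seed=31, lesion_t2_offset=offset,
                               lesion_radius_range=(2.0, 3.0))
            t1, t2, truth = generate_phantom(spec)
            lesions, _, _ = segment_cross_sectional(
                t1, t2, truth.tissue_priors(), truth.brain_mask,
                truth.ventricle_mask, 1.0,
                SegmentationConfig(mixture=MixtureConfig(seed=0)))
            assert dice(lesions.mask, truth.lesion_mask) >= target, offset

    def test_no_false_positives_on_clean_phantom(self):
        spec = PhantomSpec(rng_seed=32, lesion_count=0, noise_sd=0.0)
        t1, t2, truth = generate_phantom(spec)
        lesions, _, _ = segment_cross_sectional(
            t1, t2, truth.tissue_priors(), truth.brain_mask,
            truth.ventricle_mask, 1.0,
            SegmentationConfig(mixture=MixtureConfig(seed=0)))
        assert lesions.volume_mm3 == 0.0
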