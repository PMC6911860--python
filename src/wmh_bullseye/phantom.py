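"""Synthetic brain phantom generation.

Produces paired T1-like/T2-like volumes with exact ground truth: a concentric
ellipsoidal head (background / central CSF ventricle / WM shell / GM rim),
spherical T2-hyperintense, T1-hypointense lesions planted in white matter with
a configurable periventricular concentration, longitudinal series with lesion
growth under rigid motion, and cohort covariate tables drawn from a linear
mixed model with planted group effects.

Tissue codes in ``GroundTruth.tissue_labels``: 0 background, 1 CSF/ventricle,
2 grey matter, 3 white matter.  Lobe codes: 1 frontal, 2 parietal,
3 occipital, 4 temporal, 5 subcortical.  Hemisphere codes: 1 left, 2 right.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
LOBE_CODES = {"frontal": 1, "parietal": 2, "occipital": 3, "temporal": 4,
              "subcortical": 5}
LOBE_NAMES = {v: k for k, v in LOBE_CODES.items()}
LEFT, RIGHT = 1, 2
GROUPS = ("control", "presymptomatic", "symptomatic")


class LesionPlacementError(RuntimeError):
    """Raised when no admissible lesion centre exists after bounded retries."""


def _default_tissue_means():
    # rows: (T1, T2) per tissue; arbitrary units, CSF dark on T1 / bright on T2
    return {"csf": (30.0, 100.0), "gm": (70.0, 60.0), "wm": (100.0, 45.0)}


def _default_tissue_sds():
    return {"csf": (2.0, 2.0), "gm": (2.0, 2.0), "wm": (2.0, 2.0)}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic subject.

    ``tissue_sds`` are the nominal per-class standard deviations: the scale on
    which lesion contrast ("a k-SD lesion") and downstream z-score thresholds
    are expressed.  The simulated image noise itself is N(0, ``noise_sd``)
    added to every voxel; by default the two coincide.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: dict = field(default_factory=_default_tissue_means)
    tissue_sds: dict = field(default_factory=_default_tissue_sds)
    lesion_count: int = 3
    lesion_radius_range: tuple[float, float] = (2.0, 3.5)
    periventricular_bias: float = 0.7
    lesion_t2_offset: float = 10.0
    lesion_t1_offset: float = 20.0
    noise_sd: float = 2.0
    rng_seed: int = 0
    # normalized-radius boundaries of the concentric shells
    ventricle_frac: float = 0.18
    subcortical_frac: float = 0.30
    wm_frac: float = 0.85

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        lo, hi = self.lesion_radius_range
        extent = min(n * v for n, v in zip(self.grid_shape, self.voxel_size))
        if not (0 < lo <= hi < extent):
            raise ValueError("lesion_radius_range outside grid extent")
        for t, sds in self.tissue_sds.items():
            if any(s <= 0 for s in sds):
                raise ValueError(f"tissue SD for {t!r} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.periventricular_bias <= 1.0:
            raise ValueError("periventricular_bias must lie in [0, 1]")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class GroundTruth:
    tissue_labels: np.ndarray
    lobe_labels: np.ndarray
    hemisphere_labels: np.ndarray
    lesion_mask: np.ndarray
    tiv_mm3: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_centres_mm: np.ndarray | None = None
    lesion_radii_mm: np.ndarray | None = None

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.tissue_labels == CSF

    @property
    def wm_mask(self) -> np.ndarray:
        return self.tissue_labels == WM

    @property
    def gm_mask(self) -> np.ndarray:
        return self.tissue_labels == GM

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_labels != BACKGROUND

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def lesion_volume_mm3(self) -> float:
        return float(self.lesion_mask.sum()) * self.voxel_volume_mm3

    def tissue_priors(self) -> dict[str, np.ndarray]:
        """Hard ground-truth labels as (noise-free) spatial prior maps."""
        return {
            "csf": (self.tissue_labels == CSF).astype(float),
            "gm": (self.tissue_labels == GM).astype(float),
            "wm": (self.tissue_labels == WM).astype(float),
        }


def _coords_mm(shape, voxel_size):
    """Voxel-centre coordinates relative to the grid centre, in mm."""
    centre = (np.asarray(shape) - 1) / 2.0
    axes = [(np.arange(n) - c) * v for n, c, v in
            zip(shape, centre, voxel_size)]
    return np.meshgrid(*axes, indexing="ij")


def _normalized_radius(spec: PhantomSpec):
    dx, dy, dz = _coords_mm(spec.grid_shape, spec.voxel_size)
    semi = [0.45 * n * v for n, v in zip(spec.grid_shape, spec.voxel_size)]
    # slightly anisotropic head so no axis is privileged by symmetry
    semi = (semi[0], 0.94 * semi[1], 0.88 * semi[2])
    return np.sqrt((dx / semi[0]) ** 2 + (dy / semi[1]) ** 2
                   + (dz / semi[2]) ** 2), (dx, dy, dz)


def _make_geometry(spec: PhantomSpec):
    rho, (dx, dy, dz) = _normalized_radius(spec)
    tissue = np.full(spec.grid_shape, BACKGROUND, dtype=np.int16)
    tissue[rho <= 1.0] = GM
    tissue[rho <= spec.wm_frac] = WM
    tissue[rho <= spec.ventricle_frac] = CSF

    # dominant-axis angular sectors about the ventricle centroid
    lobes = np.zeros(spec.grid_shape, dtype=np.int16)
    ax, ay, az = np.abs(dx), np.abs(dy), np.abs(dz)
    frontal = (dy >= 0) & (ay >= ax) & (ay >= az)
    occipital = (dy < 0) & (ay >= ax) & (ay >= az)
    parietal = (dz >= 0) & (az > ay) & (az >= ax)
    inside = tissue > CSF
    lobes[inside] = LOBE_CODES["temporal"]
    lobes[inside & frontal] = LOBE_CODES["frontal"]
    lobes[inside & occipital] = LOBE_CODES["occipital"]
    lobes[inside & parietal] = LOBE_CODES["parietal"]
    band = inside & (rho <= spec.subcortical_frac)
    lobes[band] = LOBE_CODES["subcortical"]

    hemi = np.zeros(spec.grid_shape, dtype=np.int16)
    hemi[inside & (dx < 0)] = LEFT
    hemi[inside & (dx >= 0)] = RIGHT
    depth = np.clip((rho - spec.ventricle_frac)
                    / (spec.wm_frac - spec.ventricle_frac), 0.0, 1.0)
    return tissue, lobes, hemi, depth


def _sample_lesions(spec: PhantomSpec, tissue, depth, rng):
    """Plant non-overlapping spheres fully inside WM.

    Centre depth follows density ∝ (1−d)^k with k = 5·periventricular_bias
    (inverse-transform sampled), which concentrates lesions near the
    ventricles for bias → 1 and is uniform for bias = 0.
    """
    wm = tissue == WM
    interior_dist = ndi.distance_transform_edt(wm, sampling=spec.voxel_size)
    coords = _coords_mm(spec.grid_shape, spec.voxel_size)
    k = 5.0 * spec.periventricular_bias
    centres, radii = [], []
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for _ in range(spec.lesion_count):
        radius = rng.uniform(*spec.lesion_radius_range)
        eligible = interior_dist >= radius
        if not eligible.any():
            raise LesionPlacementError(
                f"no WM voxel can host a lesion of radius {radius:.2f} mm")
        idx = np.flatnonzero(eligible.ravel())
        d_elig = depth.ravel()[idx]
        placed = False
        for _attempt in range(200):
            u = rng.random()
            target_d = 1.0 - (1.0 - u) ** (1.0 / (k + 1.0))
            near = idx[np.abs(d_elig - target_d) <= 0.05]
            if near.size == 0:
                near = idx[np.argsort(np.abs(d_elig - target_d))[:32]]
            choice = near[rng.integers(near.size)]
            centre = np.array(np.unravel_index(choice, spec.grid_shape))
            c_mm = np.array([coords[a].ravel()[choice] for a in range(3)])
            if all(np.linalg.norm(c_mm - p) > radius + r + 1.0
                   for p, r in zip(centres, radii)):
                centres.append(c_mm)
                radii.append(radius)
                dist2 = sum((coords[a] - c_mm[a]) ** 2 for a in range(3))
                mask |= dist2 <= radius ** 2
                placed = True
                break
        if not placed:
            raise LesionPlacementError(
                "could not place a non-overlapping lesion after 200 retries")
    mask &= wm
    return mask, np.array(centres).reshape(-1, 3), np.asarray(radii)


def generate_phantom(spec: PhantomSpec):
    """Build one (t1, t2, truth) phantom triple, bit-reproducible per seed."""
    rng = np.random.default_rng(spec.rng_seed)
    tissue, lobes, hemi, depth = _make_geometry(spec)
    if spec.lesion_count > 0:
        lesion_mask, centres, radii = _sample_lesions(spec, tissue, depth, rng)
    else:
        lesion_mask = np.zeros(spec.grid_shape, dtype=bool)
        centres = np.zeros((0, 3))
        radii = np.zeros(0)

    t1 = np.zeros(spec.grid_shape)
    t2 = np.zeros(spec.grid_shape)
    for name, code in (("csf", CSF), ("gm", GM), ("wm", WM)):
        m1, m2 = spec.tissue_means[name]
        sel = tissue == code
        t1[sel] = m1
        t2[sel] = m2
    t1[lesion_mask] -= spec.lesion_t1_offset
    t2[lesion_mask] += spec.lesion_t2_offset
    if spec.noise_sd > 0:
        t1 = t1 + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        t2 = t2 + rng.normal(0.0, spec.noise_sd, spec.grid_shape)

    tiv = float((tissue != BACKGROUND).sum()) * spec.voxel_volume_mm3
    truth = GroundTruth(tissue_labels=tissue, lobe_labels=lobes,
                        hemisphere_labels=hemi, lesion_mask=lesion_mask,
                        tiv_mm3=tiv, voxel_size=spec.voxel_size,
                        lesion_centres_mm=centres, lesion_radii_mm=radii)
    return t1, t2, truth


def _rigid_matrix(rotation_deg):
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


def apply_rigid(volume, translation_vox=(0.0, 0.0, 0.0),
                rotation_deg=(0.0, 0.0, 0.0), order=1):
    """Resample a volume under a rigid motion about the grid centre.

    ``translation_vox`` moves the object by that many voxels along each axis;
    ``order=0`` gives nearest-neighbour (for label volumes), ``order=1``
    trilinear.
    """
    rot = _rigid_matrix(rotation_deg)
    centre = (np.asarray(volume.shape) - 1) / 2.0
    # pull transform: sample input at R^-1 (x - c - t) + c
    inv = rot.T
    offset = centre - inv @ (centre + np.asarray(translation_vox, float))
    return ndi.affine_transform(np.asarray(volume, float), inv, offset=offset,
                                order=order, mode="constant", cval=0.0,
                                prefilter=False)


def generate_longitudinal_series(spec: PhantomSpec, n_visits: int,
                                 growth_per_visit: float = 0.0,
                                 rigid_offsets=None):
    """Longitudinal phantom series with lesion growth under rigid motion.

    Lesion centres are fixed across visits (same seed for the geometry);
    radii grow by ``growth_per_visit`` mm per visit.  Each visit's volumes
    and truth labels are resampled under its rigid offset
    ``(translation_vox, rotation_deg)``; visit noise fields are independent.
    Returns a list of ``(t1, t2, truth)``.
    """
    if n_visits < 2:
        raise ValueError("a longitudinal series needs at least 2 visits")
    if rigid_offsets is None:
        rigid_offsets = [((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))] * n_visits
    if len(rigid_offsets) != n_visits:
        raise ValueError("one rigid offset per visit required")
    noise_seeds = np.random.SeedSequence(spec.rng_seed).generate_state(
        n_visits + 1)[1:] % (2 ** 31)

    # fixed lesion centres: geometry is drawn once, radii regrown per visit
    base = replace(spec, noise_sd=0.0)
    _, _, base_truth = generate_phantom(base)
    coords = _coords_mm(spec.grid_shape, spec.voxel_size)
    wm = base_truth.tissue_labels == WM

    out = []
    for v, ((trans, rot), nseed) in enumerate(zip(rigid_offsets, noise_seeds)):
        radii = (base_truth.lesion_radii_mm + v * growth_per_visit
                 if base_truth.lesion_radii_mm.size else
                 base_truth.lesion_radii_mm)
        lesion = np.zeros(spec.grid_shape, dtype=bool)
        for c_mm, r in zip(base_truth.lesion_centres_mm, radii):
            dist2 = sum((coords[a] - c_mm[a]) ** 2 for a in range(3))
            lesion |= dist2 <= r ** 2
        lesion &= wm
        t1 = np.zeros(spec.grid_shape)
        t2 = np.zeros(spec.grid_shape)
        for name, code in (("csf", CSF), ("gm", GM), ("wm", WM)):
            m1, m2 = spec.tissue_means[name]
            sel = base_truth.tissue_labels == code
            t1[sel] = m1
            t2[sel] = m2
        t1[lesion] -= spec.lesion_t1_offset
        t2[lesion] += spec.lesion_t2_offset
        truth = GroundTruth(tissue_labels=base_truth.tissue_labels.copy(),
                            lobe_labels=base_truth.lobe_labels.copy(),
                            hemisphere_labels=base_truth.hemisphere_labels
                            .copy(),
                            lesion_mask=lesion, tiv_mm3=base_truth.tiv_mm3,
                            voxel_size=spec.voxel_size,
                            lesion_centres_mm=base_truth.lesion_centres_mm,
                            lesion_radii_mm=radii)
        _check_offset_in_grid(spec, trans, rot)
        moved = any(abs(x) > 0 for x in trans) or any(abs(r) > 0 for r in rot)
        if moved:
            t1 = apply_rigid(t1, trans, rot, order=1)
            t2 = apply_rigid(t2, trans, rot, order=1)
            tissue = apply_rigid(truth.tissue_labels, trans, rot,
                                 order=0).astype(np.int16)
            lobes = apply_rigid(truth.lobe_labels, trans, rot,
                                order=0).astype(np.int16)
            hemi = apply_rigid(truth.hemisphere_labels, trans, rot,
                               order=0).astype(np.int16)
            lesion = apply_rigid(truth.lesion_mask, trans, rot,
                                 order=0) > 0.5
            truth = GroundTruth(tissue_labels=tissue, lobe_labels=lobes,
                                hemisphere_labels=hemi, lesion_mask=lesion,
                                tiv_mm3=truth.tiv_mm3,
                                voxel_size=truth.voxel_size,
                                lesion_centres_mm=truth.lesion_centres_mm,
                                lesion_radii_mm=truth.lesion_radii_mm)
        if spec.noise_sd > 0:
            vrng = np.random.default_rng(int(nseed))
            t1 = t1 + vrng.normal(0.0, spec.noise_sd, spec.grid_shape)
            t2 = t2 + vrng.normal(0.0, spec.noise_sd, spec.grid_shape)
        out.append((t1, t2, truth))
    return out


def _check_offset_in_grid(spec, trans, rot):
    """Error out if the rigid offset pushes the head outside the grid."""
    semi = [0.45 * n for n in spec.grid_shape]
    centre = (np.asarray(spec.grid_shape) - 1) / 2.0
    corners = np.array([(sx * semi[0], sy * semi[1], sz * semi[2])
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    rotm = _rigid_matrix(rot)
    moved = corners @ rotm.T + centre + np.asarray(trans, float)
    hi = np.asarray(spec.grid_shape) - 1
    if (moved < -0.5).any() or (moved > hi + 0.5).any():
        raise ValueError("rigid offset moves the head outside the grid")


# --------------------------------------------------------------------------
# cohort simulation


def _default_group_sizes():
    return {"control": 203, "presymptomatic": 101, "symptomatic": 32}


def _default_group_excess():
    # multiplicative lesion-load excess over controls, on the log scale
    return {"control": 0.0, "presymptomatic": np.log(1.178),
            "symptomatic": np.log(1.482)}


def _default_accrual():
    # log-volume slope per year per group
    return {"control": np.log(1.0432), "presymptomatic": np.log(1.0168),
            "symptomatic": np.log(1.0916)}


_AGE_BY_GROUP = {"control": (46.5, 13.4), "presymptomatic": (45.5, 11.6),
                 "symptomatic": (64.4, 8.5)}
_EDU_BY_GROUP = {"control": (14.3, 3.3), "presymptomatic": (14.8, 3.6),
                 "symptomatic": (11.6, 3.6)}
_PFEMALE = {"control": 117 / 203, "presymptomatic": 65 / 101,
            "symptomatic": 18 / 32}
_NFL = {"control": (13.3, 17.7), "presymptomatic": (11.6, 9.4),
        "symptomatic": (80.1, 42.6)}
_GFAP = {"control": (125.4, 64.4), "presymptomatic": (136.3, 69.0),
         "symptomatic": (311.8, 170.6)}
_TMEM = {"control": (6, 49, 36), "presymptomatic": (1, 27, 11),
         "symptomatic": (1, 3, 6)}  # CC:TC:TT counts
_SCANNERS = (("GE_MR750", 3), ("Philips_Achieva", 108), ("Siemens_Prisma", 51),
             ("Siemens_Skyra", 72), ("Siemens_Trio", 102))
_COG_TESTS = {"tmt_a": {"control": -0.2, "presymptomatic": 0.0,
                        "symptomatic": 2.6},
              "tmt_b": {"control": -0.2, "presymptomatic": -0.1,
                        "symptomatic": 2.0},
              "digit_span": {"control": 0.0, "presymptomatic": -0.1,
                             "symptomatic": -1.6},
              "digit_symbol": {"control": 0.3, "presymptomatic": 0.2,
                               "symptomatic": -2.1}}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative parameters for the covariate table.

    Log lesion volume follows a two-level linear mixed model:
    ``y_ij = μ + γ_g + b0_i + (α_g + b1_i)·t_ij + ε_ij`` with subject random
    intercept ``b0`` and slope ``b1``.  Covariate distributions default to the
    study demographics (group sizes, age, sex ratio, scanner mix, plasma
    markers, genotype frequencies); ``cognition_loading`` optionally ties
    cognitive z-scores to the subject's lesion-load deviation so planted
    brain–behaviour associations can be recovered downstream.
    """

    n_per_group: dict = field(default_factory=_default_group_sizes)
    baseline_log_volume_mean: float = np.log(925.9)
    group_excess: dict = field(default_factory=_default_group_excess)
    annual_accrual: dict = field(default_factory=_default_accrual)
    random_intercept_sd: float = 0.55
    random_slope_sd: float = 0.03
    residual_sd: float = 0.12
    tiv_mean_mm3: float = 1.4e6
    tiv_sd_mm3: float = 1.3e5
    visits_per_subject: int = 2
    visit_interval_years: float = 1.0
    cognition_loading: float = 0.0
    nfl_loading: float = 0.0
    voxel_volume_mm3: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        for s in (self.random_intercept_sd, self.random_slope_sd,
                  self.residual_sd):
            if s < 0:
                raise ValueError("standard deviations must be >= 0")
        for g in self.n_per_group:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")


def _lognormal_params(mean, sd):
    """Moment-match a lognormal to a positive marker's mean/SD."""
    var = np.log1p((sd / mean) ** 2)
    return np.log(mean) - var / 2, np.sqrt(var)


def generate_cohort_table(cspec: CohortSpec) -> pd.DataFrame:
    """One row per subject-visit, with planted mixed-model lesion dynamics."""
    rng = np.random.default_rng(cspec.rng_seed)
    scanner_names = [s for s, _ in _SCANNERS]
    scanner_p = np.array([n for _, n in _SCANNERS], float)
    scanner_p /= scanner_p.sum()

    rows = []
    sid = 0
    for group in GROUPS:
        n = cspec.n_per_group.get(group, 0)
        for _ in range(n):
            sid += 1
            age = rng.normal(*_AGE_BY_GROUP[group])
            sex = "F" if rng.random() < _PFEMALE[group] else "M"
            edu = rng.normal(*_EDU_BY_GROUP[group])
            scanner = scanner_names[rng.choice(len(scanner_names),
                                               p=scanner_p)]
            tiv = rng.normal(cspec.tiv_mean_mm3, cspec.tiv_sd_mm3)
            tmem_counts = np.array(_TMEM[group], float)
            tmem = ("CC", "TC", "TT")[rng.choice(3, p=tmem_counts
                                                 / tmem_counts.sum())]
            mu, sig = _lognormal_params(*_NFL[group])
            nfl = rng.lognormal(mu, sig)
            mu, sig = _lognormal_params(*_GFAP[group])
            gfap = rng.lognormal(mu, sig)
            interval = rng.uniform(0.0, 1.0)

            b0 = rng.normal(0.0, cspec.random_intercept_sd)
            b1 = rng.normal(0.0, cspec.random_slope_sd)
            # lesion-load deviation from the group mean, drives planted
            # cognition / marker associations
            dev = b0
            nfl *= np.exp(cspec.nfl_loading * dev)
            cog = {t: _COG_TESTS[t][group] + cspec.cognition_loading * dev
                   + rng.normal(0.0, 0.5) for t in _COG_TESTS}

            for v in range(cspec.visits_per_subject):
                t = v * cspec.visit_interval_years
                y = (cspec.baseline_log_volume_mean
                     + cspec.group_excess.get(group, 0.0) + b0
                     + (cspec.annual_accrual.get(group, 0.0) + b1) * t
                     + rng.normal(0.0, cspec.residual_sd))
                rows.append({
                    "subject_id": f"S{sid:04d}", "group": group,
                    "age": age + t, "sex": sex, "education": edu,
                    "scanner": scanner, "tiv_mm3": tiv,
                    "visit": v, "visit_time": t,
                    "log_wmh": y,
                    "wmh_mm3": max(np.exp(y) - cspec.voxel_volume_mm3, 0.0),
                    "nfl_pg_ml": nfl, "gfap_pg_ml": gfap,
                    "tmem106b": tmem, "sample_scan_interval": interval,
                    **{k: cog[k] for k in _COG_TESTS},
                })
    return pd.DataFrame(rows)
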