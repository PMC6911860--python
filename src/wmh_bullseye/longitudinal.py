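"""Longitudinal lesion segmentation constrained by a within-subject average.

All visits are iteratively co-registered (rigid, with a translations-only
first pass so the allowed degrees of freedom grow over iterations) and
intensity-rescaled to an evolving average image.  The intensity mixture is
fitted once on that average; each visit is then segmented with the model
structure frozen and its parameters tethered to the average-image fit, which
damps visit-to-visit measurement noise.  Lesion masks are produced in each
visit's native space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize

from .mixture import fit_mixture
from .phantom import _rigid_matrix
from .segmentation import (SegmentationConfig, classify_components,
                           select_candidates)


class RegistrationDivergence(RuntimeError):
    """Groupwise cost increased over three consecutive iterations."""


def load_series_manifest(path):
    """Build a :class:`VisitSeries` from a manifest CSV.

    Expected columns: ``subject_id, visit, t1_path, t2_path, time_years``;
    rows are ordered by time.  Returns ``{subject_id: VisitSeries}``.
    """
    import pandas as pd

    from . import io as wio

    df = pd.read_csv(path)
    required = {"subject_id", "visit", "t1_path", "t2_path", "time_years"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    df = df.sort_values(["subject_id", "time_years"])
    out = {}
    for sid, g in df.groupby("subject_id"):
        t1s = [wio.load_nifti(p)[0] for p in g.t1_path]
        t2s = [wio.load_nifti(p)[0] for p in g.t2_path]
        out[sid] = VisitSeries(t1s, t2s, list(g.time_years))
    return out


@dataclass(frozen=True)
class RigidTransform:
    """Object motion: rotation about the grid centre then translation (vox)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def params(self) -> np.ndarray:
        return np.array(list(self.translation) + list(self.rotation_deg))

    @property
    def is_identity(self) -> bool:
        """True when the motion is below interpolation resolution
        (0.05 voxel / 0.05°), in which case resampling is skipped."""
        return bool(np.abs(self.params).max() < 0.05)

    def apply(self, volume, order: int = 1) -> np.ndarray:
        """Resample ``volume`` so its content moves by this transform."""
        if self.is_identity:
            return np.asarray(volume, float).copy()
        rot = _rigid_matrix(self.rotation_deg)
        centre = (np.asarray(volume.shape) - 1) / 2.0
        inv = rot.T
        offset = centre - inv @ (centre
                                 + np.asarray(self.translation, float))
        return ndi.affine_transform(np.asarray(volume, float), inv,
                                    offset=offset, order=order,
                                    mode="constant", cval=0.0,
                                    prefilter=False)

    def inverse(self) -> "RigidTransform":
        rot = _rigid_matrix(self.rotation_deg)
        inv_t = -(rot.T @ np.asarray(self.translation, float))
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        # for the small angles used here the inverse of Rz·Ry·Rx is well
        # approximated by negated angles; refine translation exactly
        return RigidTransform(tuple(inv_t), tuple(-r for r in
                                                  self.rotation_deg))


@dataclass
class VisitSeries:
    t1s: list
    t2s: list
    times: list
    transforms: list = field(default_factory=list)   # visit -> average space
    gains: list = field(default_factory=list)
    average_t1: np.ndarray | None = None
    average_t2: np.ndarray | None = None

    def __post_init__(self):
        # a 1-visit "series" is tolerated so callers can fall back to the
        # cross-sectional path; averaging itself needs >= 2 visits
        if len(self.t1s) < 1:
            raise ValueError("a visit series needs at least 1 visit")
        if not all(b > a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("acquisition times must be strictly increasing")


def register_rigid(moving, fixed, init=None, dof: str = "rigid",
                   mask=None) -> RigidTransform:
    """Rigid (or translation-only) registration by mean-squared error.

    Returns the transform that moves ``moving``'s content onto ``fixed``.
    Optimized with Nelder-Mead over (tx, ty, tz[, rx, ry, rz]).
    """
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    sel = np.ones(fixed.shape, bool) if mask is None else np.asarray(mask,
                                                                     bool)
    x0 = np.zeros(6) if init is None else np.asarray(init, float).copy()

    def cost(p):
        tr = RigidTransform(tuple(p[:3]), tuple(p[3:6]))
        return float(((tr.apply(moving) - fixed)[sel] ** 2).mean())

    def simplex(x, step=0.5):
        # half-voxel / half-degree exploration: wide enough to escape the
        # sub-resolution identity plateau
        pts = [x]
        for j in range(len(x)):
            e = x.copy()
            e[j] += step
            pts.append(e)
        return np.array(pts)

    if dof == "translation":
        def cost_t(p3):
            return cost(np.concatenate([p3, x0[3:6]]))
        res = minimize(cost_t, x0[:3], method="Nelder-Mead",
                       options={"xatol": 5e-3, "fatol": 1e-8,
                                "maxiter": 200,
                                "initial_simplex": simplex(x0[:3])})
        p = np.concatenate([res.x, x0[3:6]])
    elif dof == "rigid":
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 5e-3, "fatol": 1e-8,
                                "maxiter": 400,
                                "initial_simplex": simplex(x0)})
        p = res.x
    else:
        raise ValueError("dof must be 'translation' or 'rigid'")
    return RigidTransform(tuple(p[:3]), tuple(p[3:6]))


def build_average_space(series: VisitSeries, max_iter: int = 6,
                        tol_vox: float = 0.01,
                        allow_rotation: bool = True) -> VisitSeries:
    """Groupwise registration to an evolving within-subject average.

    Iteration 1 allows translations only; later iterations use full rigid
    transforms.  After each alignment every visit is linearly
    intensity-rescaled to the current average (least-squares gain), and the
    average is recomputed as the voxelwise mean.  Converged when the mean
    transform update falls below ``tol_vox`` voxels; diverged (error) if the
    groupwise cost rises three times in a row.
    """
    n = len(series.t1s)
    if n < 2:
        raise ValueError("averaging needs at least 2 visits")
    transforms = [RigidTransform() for _ in range(n)]
    gains = [1.0 for _ in range(n)]
    avg1 = np.mean(series.t1s, axis=0)
    avg2 = np.mean(series.t2s, axis=0)
    prev_cost = np.inf
    rises = 0
    for it in range(max_iter):
        dof = "translation" if it == 0 or not allow_rotation else "rigid"
        new_transforms = []
        updates = []
        for v in range(n):
            # moving visit onto average: forward transform is the inverse of
            # the visit's motion, solved directly by registering visit->avg
            tr = register_rigid(series.t1s[v], avg1 / gains[v],
                                init=transforms[v].params, dof=dof)
            updates.append(np.abs(tr.params[:3]
                                  - transforms[v].params[:3]).mean())
            new_transforms.append(tr)
        # remove the mean motion so the average space does not drift
        mean_p = np.mean([tr.params for tr in new_transforms], axis=0)
        transforms = [RigidTransform(tuple(tr.params[:3] - mean_p[:3]),
                                     tuple(tr.params[3:] - mean_p[3:]))
                      for tr in new_transforms]
        aligned1 = [tr.apply(t1) for tr, t1 in zip(transforms, series.t1s)]
        aligned2 = [tr.apply(t2) for tr, t2 in zip(transforms, series.t2s)]
        gains = [float((avg1 * a).sum() / max((a * a).sum(), 1e-12))
                 for a in aligned1]
        gains = [g * n / sum(gains) for g in gains]  # fix overall scale
        avg1 = np.mean([g * a for g, a in zip(gains, aligned1)], axis=0)
        avg2 = np.mean([g * a for g, a in zip(gains, aligned2)], axis=0)
        cost = float(np.mean([((g * a - avg1) ** 2).mean()
                              for g, a in zip(gains, aligned1)]))
        if cost > prev_cost * (1 + 1e-9):
            rises += 1
            if rises >= 3:
                raise RegistrationDivergence(
                    f"groupwise cost increased 3x (last {cost:.4g} "
                    f"> {prev_cost:.4g})")
        else:
            rises = 0
        prev_cost = cost
        if it > 0 and float(np.mean(updates)) < tol_vox:
            break
    return VisitSeries(series.t1s, series.t2s, series.times,
                       transforms=transforms, gains=gains,
                       average_t1=avg1, average_t2=avg2)


def constrained_segment(series: VisitSeries, tissue_priors,
                        ventricle_mask, brain_mask,
                        voxel_volume_mm3: float = 1.0,
                        config: SegmentationConfig | None = None,
                        tether_strength: float = 1.0):
    """Segment each visit with the average-image mixture as anchor.

    The mixture (component counts included) is fitted on the average image;
    each visit is re-fit with parameters tethered to that model, and the
    candidate z-score statistics are taken from the average-image model so
    the operating point is common to all visits.  Masks are returned in
    native visit space.  A 1-visit series falls back to the cross-sectional
    path.
    """
    config = config or SegmentationConfig()
    if len(series.t1s) == 1:
        from .segmentation import segment_cross_sectional
        lesions, _, _ = segment_cross_sectional(
            series.t1s[0], series.t2s[0], tissue_priors, brain_mask,
            ventricle_mask, voxel_volume_mm3, config)
        return [lesions]
    if series.average_t1 is None:
        series = build_average_space(series)
    avg_model, _ = fit_mixture(series.average_t1, series.average_t2,
                               tissue_priors, brain_mask, config.mixture)
    wm_dominant = np.stack([np.asarray(tissue_priors[k], float)
                            for k in ("csf", "gm", "wm")]).argmax(axis=0) == 2
    masks = []
    for v in range(len(series.t1s)):
        tr = series.transforms[v] if series.transforms else RigidTransform()
        inv = tr.inverse()
        native_priors = {k: inv.apply(np.asarray(p, float), order=1)
                         for k, p in tissue_priors.items()}
        native_vent = inv.apply(np.asarray(ventricle_mask, float),
                                order=0) > 0.5
        native_brain = inv.apply(np.asarray(brain_mask, float), order=0) > 0.5
        _, resp = fit_mixture(series.t1s[v], series.t2s[v], native_priors,
                              native_brain, config.mixture,
                              tether_model=avg_model,
                              tether_strength=tether_strength)
        cand = select_candidates(resp, avg_model, native_priors, native_vent,
                                 config)
        native_wm = inv.apply(wm_dominant.astype(float), order=0) > 0.5
        lesions = classify_components(cand, series.t2s[v], avg_model,
                                      native_wm, voxel_volume_mm3, config)
        masks.append(lesions)
    return masks
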