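"""Bullseye subdivision of the white matter and regional volumetry.

Two complementary schemes: an angular one assigning each WM voxel to its
nearest cortical lobe (subcortical WM kept separate), and a radial one
binning the normalized ventricle-to-cortex distance into four equidistant
layers whose middle two are merged, leaving periventricular / medial /
peripheral.  Their product gives the bullseye cells.  Regional lesion and GM
volumes, a left-right asymmetry index and a tract-overlap ranking are
computed on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .phantom import LOBE_CODES, LOBE_NAMES

LOBE_ORDER = ("frontal", "parietal", "occipital", "temporal")
LAYER_NAMES = {1: "periventricular", 2: "medial", 3: "peripheral"}
LAYER_CODES = {v: k for k, v in LAYER_NAMES.items()}


@dataclass
class LayerMap:
    normalized_depth: np.ndarray
    layer_labels: np.ndarray


@dataclass
class RegionTable:
    """Regional WMH and GM volumes in mm³, with conservation identities."""

    table: pd.DataFrame   # tidy: columns region_type, region, wmh_mm3, gm_mm3
    tiv_mm3: float

    def volume(self, region_type: str, region: str,
               measure: str = "wmh_mm3") -> float:
        sel = self.table[(self.table.region_type == region_type)
                         & (self.table.region == region)]
        if sel.empty:
            raise KeyError(f"no region {region_type}/{region}")
        return float(sel[measure].iloc[0])


def assign_lobes(wm_mask, cortical_lobe_labels, subcortical_mask=None,
                 voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Label each WM voxel with the lobe of its nearest cortical voxel.

    Distance is Euclidean in mm (one distance transform per lobe); ties are
    broken deterministically in the fixed order frontal, parietal, occipital,
    temporal.  Voxels under ``subcortical_mask`` keep the subcortical label
    and never join a lobe.
    """
    wm = np.asarray(wm_mask, bool)
    lobes = np.asarray(cortical_lobe_labels)
    if wm.shape != lobes.shape:
        raise ValueError("wm_mask and cortical label grids differ")
    dists = []
    for name in LOBE_ORDER:
        cortex_l = lobes == LOBE_CODES[name]
        if cortex_l.any():
            d = ndi.distance_transform_edt(~cortex_l, sampling=voxel_size)
        else:
            d = np.full(wm.shape, np.inf)
        dists.append(d)
    nearest = np.argmin(np.stack(dists), axis=0)  # first-in-order tie-break
    out = np.zeros(wm.shape, dtype=np.int16)
    out[wm] = np.array([LOBE_CODES[LOBE_ORDER[i]] for i in range(4)],
                       dtype=np.int16)[nearest[wm]]
    if subcortical_mask is not None:
        out[np.asarray(subcortical_mask, bool) & wm] = \
            LOBE_CODES["subcortical"]
    return out


def normalized_depth(wm_mask, ventricle_mask, cortex_mask,
                     voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """d = d_v / (d_v + d_c) over the WM, 0 at the ventricles, 1 at cortex."""
    ventricle = np.asarray(ventricle_mask, bool)
    cortex = np.asarray(cortex_mask, bool)
    if not ventricle.any() or not cortex.any():
        raise ValueError("ventricle and cortex masks must be non-empty")
    d_v = ndi.distance_transform_edt(~ventricle, sampling=voxel_size)
    d_c = ndi.distance_transform_edt(~cortex, sampling=voxel_size)
    wm = np.asarray(wm_mask, bool)
    denom = d_v + d_c
    if np.any(denom[wm] == 0):
        raise ValueError("ventricular and cortical surfaces overlap "
                         "inside the WM")
    depth = np.zeros(wm.shape)
    depth[wm] = d_v[wm] / denom[wm]
    return depth


def make_layers(depth, wm_mask=None) -> np.ndarray:
    """Quartile depth bins with the middle two merged.

    [0, 0.25) periventricular, [0.25, 0.75) medial, [0.75, 1] peripheral;
    a depth of exactly 0.25 or 0.75 falls in the outer of the two bins.
    """
    depth = np.asarray(depth, float)
    wm = np.ones(depth.shape, bool) if wm_mask is None \
        else np.asarray(wm_mask, bool)
    d = depth[wm]
    if d.size and (d.min() < 0 or d.max() > 1):
        raise ValueError("depth values must lie in [0, 1]")
    labels = np.zeros(depth.shape, dtype=np.int16)
    labels[wm] = np.where(d < 0.25, LAYER_CODES["periventricular"],
                          np.where(d < 0.75, LAYER_CODES["medial"],
                                   LAYER_CODES["peripheral"]))
    return labels


def regional_volumes(lesion_mask, gm_mask, lobe_labels, layer_labels,
                     hemisphere_labels, voxel_volume_mm3: float,
                     tiv_mm3: float = np.nan) -> RegionTable:
    """Tidy table of WMH and GM volumes per lobe, layer, cell, hemisphere."""
    lesion = np.asarray(lesion_mask, bool)
    gm = np.asarray(gm_mask, bool)
    for arr in (gm, lobe_labels, layer_labels, hemisphere_labels):
        if np.asarray(arr).shape != lesion.shape:
            raise ValueError("all label volumes must share the lesion grid")
    lobe_labels = np.asarray(lobe_labels)
    layer_labels = np.asarray(layer_labels)
    hemis = np.asarray(hemisphere_labels)
    vv = float(voxel_volume_mm3)

    rows = [{"region_type": "total", "region": "total",
             "wmh_mm3": lesion.sum() * vv, "gm_mm3": gm.sum() * vv}]
    for name, code in LOBE_CODES.items():
        sel = lobe_labels == code
        rows.append({"region_type": "lobe", "region": name,
                     "wmh_mm3": (lesion & sel).sum() * vv,
                     "gm_mm3": (gm & sel).sum() * vv})
    for code, name in LAYER_NAMES.items():
        sel = layer_labels == code
        rows.append({"region_type": "layer", "region": name,
                     "wmh_mm3": (lesion & sel).sum() * vv,
                     "gm_mm3": (gm & sel).sum() * vv})
    for lname, lcode in LOBE_CODES.items():
        for ycode, yname in LAYER_NAMES.items():
            sel = (lobe_labels == lcode) & (layer_labels == ycode)
            rows.append({"region_type": "cell",
                         "region": f"{lname}_{yname}",
                         "wmh_mm3": (lesion & sel).sum() * vv,
                         "gm_mm3": (gm & sel).sum() * vv})
    for hname, hcode in (("left", 1), ("right", 2)):
        sel = hemis == hcode
        rows.append({"region_type": "hemisphere", "region": hname,
                     "wmh_mm3": (lesion & sel).sum() * vv,
                     "gm_mm3": (gm & sel).sum() * vv})
    df = pd.DataFrame(rows)
    for col in ("wmh_mm3", "gm_mm3"):
        df[col] = df[col].astype(float)
    return RegionTable(df, float(tiv_mm3))


def asymmetry_index(left_volume: float, right_volume: float) -> float:
    """(L − R) / (L + R): the signed left-right load imbalance in [−1, 1]."""
    if left_volume < 0 or right_volume < 0:
        raise ValueError("volumes must be non-negative")
    total = left_volume + right_volume
    if total == 0:
        raise ValueError("asymmetry undefined for two empty hemispheres")
    return (left_volume - right_volume) / total


def rank_tract_overlap(lesion_mask, tract_atlas: dict,
                       threshold: float = 0.25) -> list[tuple[str, int]]:
    """Tracts ranked by the number of lesion voxels they pass through.

    ``tract_atlas`` maps tract name → probabilistic volume; a lesion voxel
    counts toward a tract where the tract probability exceeds ``threshold``.
    Ties are broken alphabetically.
    """
    if not tract_atlas:
        raise ValueError("empty tract atlas")
    lesion = np.asarray(lesion_mask, bool)
    counts = {}
    for name, vol in tract_atlas.items():
        vol = np.asarray(vol, float)
        if vol.shape != lesion.shape:
            raise ValueError(f"tract {name!r} not on the lesion grid")
        counts[name] = int((lesion & (vol > threshold)).sum())
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def bullseye_parcellation(truth_or_masks, voxel_size=(1.0, 1.0, 1.0)):
    """Convenience: lobes + depth + layers from a GroundTruth-like object."""
    t = truth_or_masks
    cortical = np.where(t.gm_mask, t.lobe_labels, 0)
    lobe = assign_lobes(t.wm_mask, cortical,
                        t.lobe_labels == LOBE_CODES["subcortical"],
                        voxel_size)
    # cortical voxels keep their own lobe so lobar GM volumes are defined
    lobe = np.where(t.gm_mask, t.lobe_labels, lobe).astype(np.int16)
    depth = normalized_depth(t.wm_mask, t.ventricle_mask, t.gm_mask,
                             voxel_size)
    layers = make_layers(depth, t.wm_mask)
    return lobe, LayerMap(depth, layers)
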