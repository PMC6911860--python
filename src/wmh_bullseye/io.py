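"""NIfTI and table I/O helpers (nibabel-backed)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(volume, path, voxel_size=(1.0, 1.0, 1.0), dtype=None):
    volume = np.asarray(volume)
    if dtype is not None:
        volume = volume.astype(dtype)
    elif volume.dtype == bool:
        volume = volume.astype(np.uint8)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))
    return Path(path)


def load_nifti(path):
    """Returns (data, voxel_size) from a NIfTI file."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])
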