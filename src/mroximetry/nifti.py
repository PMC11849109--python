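"""Thin NIfTI read/write helpers shared by the CLI surface."""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["load_volume", "save_volume"]


def load_volume(path, dtype=float) -> np.ndarray:
    """Load a NIfTI volume as an array (boolean masks via ``dtype=bool``)."""
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return data.astype(dtype)


def save_volume(data, path, voxel_size_mm: float = 1.0) -> None:
    """Save an array as NIfTI with an isotropic diagonal affine."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
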