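"""NIfTI round-trips for volumes and masks (nibabel-backed).

Arrays are stored in (z, y, x) axis order with a diagonal affine carrying
the voxel spacing; image and mask of one case share the same affine.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np

from .preprocess import CTVolume, MaskVolume

PathLike = Union[str, Path]


def _affine(spacing_mm: Tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def save_volume(vol: CTVolume, path: PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing_mm))
    nib.save(img, str(path))


def save_mask(mask: MaskVolume, spacing_mm: Tuple[float, float, float], path: PathLike) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(spacing_mm))
    nib.save(img, str(path))


def load_volume(path: PathLike, intensity_space: str = "HU") -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(np.asarray(img.dataobj, dtype=np.float32), spacing, intensity_space)


def load_mask(path: PathLike) -> MaskVolume:
    img = nib.load(str(path))
    return MaskVolume(np.rint(np.asarray(img.dataobj)).astype(np.uint8))


def load_spacing(path: PathLike) -> Tuple[float, float, float]:
    img = nib.load(str(path))
    return tuple(float(z) for z in img.header.get_zooms()[:3])
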