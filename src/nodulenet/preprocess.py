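"""CT preprocessing chain: isotropic resampling, HU clipping/normalization,
lesion-centered patch extraction, and training-time augmentation.

The chain mirrors standard thin-slice lung-CT practice: volumes are
resampled to 1 mm isotropic spacing (image trilinear, mask nearest
neighbor), intensities are clipped to [-1000, 400] HU — the range that
retains pulmonary structures — and mapped linearly to [0, 1], and 64³
patches centered on the target lesion are cut out for the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

HU_MIN = -1000.0
HU_MAX = 400.0
PATCH_SIZE = 64


class ValidationError(ValueError):
    pass


@dataclass
class CTVolume:
    """Dense 3-D scalar field with physical spacing (axis order z, y, x)."""

    data: np.ndarray
    spacing_mm: Tuple[float, float, float]
    intensity_space: str = "HU"  # {"HU", "normalized"}

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if self.intensity_space not in ("HU", "normalized"):
            raise ValidationError(f"unknown intensity space {self.intensity_space!r}")
        if self.intensity_space == "normalized":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValidationError(f"normalized volume outside [0,1]: [{lo}, {hi}]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class MaskVolume:
    """Binary mask aligned voxel-for-voxel with its CTVolume."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"mask must be binary, found values {vals}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabeledPatch:
    """Network-ready patch: normalized image, aligned mask, malignancy label."""

    image: np.ndarray
    mask: np.ndarray
    label: int
    case_id: str = ""
    center: Tuple[int, int, int] = (0, 0, 0)
    size: int = PATCH_SIZE

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask)
        s = self.size
        if self.image.shape != (s, s, s) or self.mask.shape != (s, s, s):
            raise ValidationError(
                f"patch must be ({s},{s},{s}), got image {self.image.shape}, mask {self.mask.shape}"
            )
        if self.image.min() < -1e-6 or self.image.max() > 1 + 1e-6:
            raise ValidationError("patch image must lie in [0,1]")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"patch mask must be binary, found {vals}")
        self.mask = self.mask.astype(np.uint8)
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample_isotropic(
    vol: CTVolume,
    mask: Optional[MaskVolume] = None,
    target_mm: float = 1.0,
) -> Tuple[CTVolume, Optional[MaskVolume]]:
    """Resample to isotropic `target_mm` spacing.

    Output shape per axis is round(shape * spacing / target). The image is
    interpolated trilinearly, the mask nearest-neighbor (stays binary).
    """
    if target_mm <= 0:
        raise ValidationError("target spacing must be positive")
    if mask is not None and mask.shape != vol.shape:
        raise ValidationError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    in_shape = np.array(vol.shape)
    spacing = np.array(vol.spacing_mm)
    out_shape = np.round(in_shape * spacing / target_mm).astype(int)
    out_shape = np.maximum(out_shape, 1)

    # output voxel j sits at physical coordinate j * target; map to input index
    grids = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    coords = np.stack(grids)
    img = ndimage.map_coordinates(
        vol.data.astype(np.float64), coords, order=1, mode="nearest"
    ).astype(vol.data.dtype if vol.data.dtype.kind == "f" else np.float32)
    out_vol = CTVolume(img, (target_mm,) * 3, vol.intensity_space)
    out_mask = None
    if mask is not None:
        m = ndimage.map_coordinates(mask.data, coords, order=0, mode="nearest")
        out_mask = MaskVolume(m)
    return out_vol, out_mask


def clip_normalize_hu(vol: CTVolume) -> CTVolume:
    """Clip to [-1000, 400] HU and map linearly onto [0, 1]."""
    if vol.intensity_space != "HU":
        raise ValidationError("volume is already normalized")
    clipped = np.clip(vol.data, HU_MIN, HU_MAX)
    out = (clipped - HU_MIN) / (HU_MAX - HU_MIN)
    return CTVolume(out.astype(np.float32), vol.spacing_mm, "normalized")


def extract_patch(
    vol: CTVolume,
    mask: MaskVolume,
    center: Tuple[int, int, int],
    label: int = 0,
    case_id: str = "",
    size: int = PATCH_SIZE,
) -> LabeledPatch:
    """Cut a size³ patch centered on `center`.

    Even-size convention: the center voxel lands at index size // 2 on each
    axis. Out-of-bounds regions are zero-padded (0.0 = air after
    normalization).
    """
    if vol.intensity_space != "normalized":
        raise ValidationError("extract_patch expects a normalized volume")
    if mask.shape != vol.shape:
        raise ValidationError("mask/volume shape mismatch")
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= n for c, n in zip(center, vol.shape)):
        raise IndexError(f"center {center} outside volume of shape {vol.shape}")
    half = size // 2
    img = np.zeros((size,) * 3, dtype=np.float32)
    msk = np.zeros((size,) * 3, dtype=np.uint8)
    src, dst = [], []
    for c, n in zip(center, vol.shape):
        lo, hi = c - half, c - half + size
        src.append(slice(max(lo, 0), min(hi, n)))
        dst.append(slice(max(lo, 0) - lo, min(hi, n) - lo))
    img[tuple(dst)] = vol.data[tuple(src)]
    msk[tuple(dst)] = mask.data[tuple(src)]
    return LabeledPatch(img, msk, label, case_id=case_id, center=center, size=size)


@dataclass(frozen=True)
class AugmentConfig:
    """Per-transform application probabilities and strengths."""

    p_rotate: float = 0.5       # axis-aligned 90-degree rotations
    p_flip: float = 0.5         # axis flips
    p_elastic: float = 0.3
    p_noise: float = 0.3
    noise_sigma: float = 0.02   # on the normalized [0,1] scale
    elastic_alpha: float = 2.0  # displacement amplitude, voxels
    elastic_sigma: float = 6.0  # smoothing of the displacement field, voxels

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(p_rotate=0.0, p_flip=0.0, p_elastic=0.0, p_noise=0.0)


def augment_patch(patch: LabeledPatch, params: AugmentConfig, seed: int) -> LabeledPatch:
    """Apply the four augmentations, each with its configured probability.

    Image and mask receive identical geometric transforms (rotation,
    flips, elastic deformation); Gaussian noise perturbs the image only
    and the result is re-clipped to [0, 1]. The label never changes.
    """
    rng = np.random.default_rng(seed)
    img = patch.image.copy()
    msk = patch.mask.copy()

    if rng.random() < params.p_rotate:
        axes = tuple(rng.choice(3, size=2, replace=False))
        k = int(rng.integers(1, 4))
        img = np.rot90(img, k=k, axes=axes)
        msk = np.rot90(msk, k=k, axes=axes)

    if rng.random() < params.p_flip:
        axis = int(rng.integers(0, 3))
        img = np.flip(img, axis=axis)
        msk = np.flip(msk, axis=axis)

    if rng.random() < params.p_elastic:
        shape = img.shape
        disp = [
            ndimage.gaussian_filter(
                rng.uniform(-1, 1, shape), params.elastic_sigma, mode="constant"
            )
            for _ in range(3)
        ]
        norm = max(max(np.abs(d).max() for d in disp), 1e-12)
        grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
        coords = np.stack([g + params.elastic_alpha * d / norm for g, d in zip(grids, disp)])
        img = ndimage.map_coordinates(img, coords, order=1, mode="nearest").astype(np.float32)
        msk = ndimage.map_coordinates(msk, coords, order=0, mode="nearest")

    if rng.random() < params.p_noise:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape).astype(np.float32)
        img = np.clip(img, 0.0, 1.0)

    return LabeledPatch(
        np.ascontiguousarray(img), np.ascontiguousarray(msk),
        patch.label, case_id=patch.case_id, center=patch.center, size=patch.size,
    )
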