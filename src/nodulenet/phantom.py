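"""Synthetic CT nodule phantoms with ground-truth masks and labels.

Each phantom is a lung-window-like volume: low-HU parenchyma background
with additive Gaussian noise and straight tubular vessel-like clutter,
containing one star-shaped nodule. The nodule surface is

    r(θ, φ) = r0 · (1 + a · s(θ, φ)),

where r0 is the base radius (mm), a < 1 the spiculation amplitude and s a
smooth zero-mean angular perturbation built from `spike_count` randomly
oriented von-Mises-like bumps — benign nodules are small and smooth,
malignant ones larger, spiculated and of higher intensity contrast, so a
classifier has a genuine morphological signal to learn. Generation is a
pure function of the spec (bit-identical for equal seeds).

Class-conditional defaults (cohort generation):

===========  ============  ==============
parameter    benign        malignant
===========  ============  ==============
r0 (mm)      U[1.5, 6]     U[5, 15]
a            U[0, 0.1]     U[0.15, 0.4]
spike_count  2–5           6–14
nodule HU    U[-100, 0]    U[0, 100]
===========  ============  ==============

Background -800 HU, noise sigma 40 HU, 2–5 vessels, 72³ volumes at 1 mm
isotropic spacing (the 3–30 mm diameter range of screening-relevant
nodules fits with margin).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import save_mask, save_volume
from .preprocess import CTVolume, MaskVolume

DEFAULT_VOLUME_SHAPE = (72, 72, 72)
DEFAULT_SPACING = (1.0, 1.0, 1.0)
MANIFEST_COLUMNS = [
    "case_id", "image_path", "mask_path", "label", "center_z", "center_y", "center_x",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic nodule phantom."""

    nodule_radius_mm: float
    spiculation_amplitude: float = 0.0
    spike_count: int = 0
    label: int = 0
    seed: int = 0
    volume_shape: Tuple[int, int, int] = DEFAULT_VOLUME_SHAPE
    spacing_mm: Tuple[float, float, float] = DEFAULT_SPACING
    nodule_hu: float = -50.0
    background_hu: float = -800.0
    noise_sigma_hu: float = 40.0
    vessel_count: int = 3
    center_voxel: Optional[Tuple[int, int, int]] = None
    edge_sigma: float = 0.7  # boundary smoothing of the rendered rim; 0 = hard edge

    def __post_init__(self):
        if not (1.5 <= self.nodule_radius_mm <= 15.0):
            raise ValueError(f"nodule_radius_mm must be in [1.5, 15], got {self.nodule_radius_mm}")
        if not (0.0 <= self.spiculation_amplitude < 1.0):
            raise ValueError("spiculation_amplitude must be in [0, 1)")
        if self.spike_count < 0 or self.vessel_count < 0:
            raise ValueError("spike_count and vessel_count must be >= 0")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (benign) or 1 (malignant)")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")

    @property
    def center(self) -> Tuple[int, int, int]:
        if self.center_voxel is not None:
            return tuple(int(c) for c in self.center_voxel)
        return tuple(int(n // 2) for n in self.volume_shape)


def _fibonacci_sphere(n: int = 512) -> np.ndarray:
    """Quasi-uniform unit directions used to center/scale the perturbation."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )


class _AngularPerturbation:
    """Smooth zero-mean field s(u) on the sphere, |s| <= 1, with lobes."""

    def __init__(self, spike_count: int, rng: np.random.Generator):
        self.spike_count = spike_count
        if spike_count > 0:
            d = rng.normal(size=(spike_count, 3))
            self.dirs = d / np.linalg.norm(d, axis=1, keepdims=True)
            self.kappa = rng.uniform(8.0, 24.0, size=spike_count)
            raw = self._raw(_fibonacci_sphere())
            self.offset = raw.mean()
            self.scale = max(np.abs(raw - self.offset).max(), 1e-12)

    def _raw(self, u: np.ndarray) -> np.ndarray:
        return np.exp(self.kappa * (u @ self.dirs.T - 1.0)).sum(axis=1)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        if self.spike_count == 0:
            return np.zeros(u.shape[0])
        return np.clip((self._raw(u) - self.offset) / self.scale, -1.0, 1.0)


def make_nodule_mask(spec: PhantomSpec) -> MaskVolume:
    """Voxelize the star-shaped nodule region into a binary mask.

    Raises :class:`GeometryError` when the nodule (at its maximal radius
    plus one voxel of margin) would cross the volume boundary. The result
    is a single 6-connected component containing the center voxel.
    """
    center = spec.center
    spacing = np.array(spec.spacing_mm)
    r_max = spec.nodule_radius_mm * (1.0 + spec.spiculation_amplitude)
    for c, n, s in zip(center, spec.volume_shape, spacing):
        if r_max + s > min(c, n - 1 - c) * s:
            raise GeometryError(
                f"nodule of max radius {r_max:.1f} mm at {center} does not fit "
                f"inside {spec.volume_shape} @ {spec.spacing_mm} mm with margin"
            )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    perturb = _AngularPerturbation(
        spec.spike_count if spec.spiculation_amplitude > 0 else 0, rng
    )

    # evaluate only inside the bounding box of the maximal radius
    lo = [max(int(np.floor(c - r_max / s)) - 1, 0) for c, s in zip(center, spacing)]
    hi = [
        min(int(np.ceil(c + r_max / s)) + 2, n)
        for c, s, n in zip(center, spacing, spec.volume_shape)
    ]
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    offsets = np.stack(
        [(g - c) * s for g, c, s in zip(grids, center, spacing)], axis=-1
    )  # (..., 3) in mm
    dist = np.linalg.norm(offsets, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(dist[..., None] > 0, offsets / dist[..., None], 0.0)
    s_val = perturb(u.reshape(-1, 3)).reshape(dist.shape)
    radius = spec.nodule_radius_mm * (1.0 + spec.spiculation_amplitude * s_val)
    box = dist <= radius

    mask = np.zeros(spec.volume_shape, dtype=np.uint8)
    mask[tuple(slice(a, b) for a, b in zip(lo, hi))] = box
    # keep the 6-connected component containing the center
    labeled, n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n_comp > 1:
        mask = (labeled == labeled[center]).astype(np.uint8)
    return MaskVolume(mask)


def render_phantom(mask: MaskVolume, spec: PhantomSpec) -> CTVolume:
    """Render the HU-valued volume around a nodule mask.

    Background at `background_hu` plus Gaussian noise; mask voxels at
    exactly `nodule_hu` (pre-noise); an optional smoothed rim just outside
    the mask blends the boundary; `vessel_count` straight tubes of
    near-nodule intensity pass close to (possibly touching) the nodule but
    are never labeled into the mask.
    """
    if mask.shape != spec.volume_shape:
        raise GeometryError(f"mask shape {mask.shape} != spec volume {spec.volume_shape}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    img = np.full(spec.volume_shape, spec.background_hu, dtype=np.float64)
    fg = mask.data.astype(bool)
    contrast = spec.nodule_hu - spec.background_hu

    if spec.edge_sigma > 0:
        alpha = ndimage.gaussian_filter(mask.data.astype(np.float64), spec.edge_sigma)
        img += np.where(fg, 0.0, alpha) * contrast

    # vessel-like tubes near the nodule
    shape = np.array(spec.volume_shape, dtype=np.float64)
    center = np.array(spec.center, dtype=np.float64)
    if spec.vessel_count > 0:
        grids = np.stack(
            np.meshgrid(*[np.arange(n, dtype=np.float64) for n in spec.volume_shape],
                        indexing="ij"),
            axis=-1,
        )
        r_vox = spec.nodule_radius_mm / min(spec.spacing_mm)
        for _ in range(spec.vessel_count):
            offset_dir = rng.normal(size=3)
            offset_dir /= np.linalg.norm(offset_dir)
            point = center + offset_dir * (r_vox + rng.uniform(1.0, 5.0))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            radius = rng.uniform(1.0, 2.0)
            rel = grids - point
            dist_line = np.linalg.norm(rel - (rel @ axis)[..., None] * axis, axis=-1)
            tube = (dist_line <= radius) & ~fg
            img[tube] = spec.nodule_hu + rng.normal(0.0, 10.0)

    img[fg] = spec.nodule_hu
    if spec.noise_sigma_hu > 0:
        img += rng.normal(0.0, spec.noise_sigma_hu, spec.volume_shape)
    return CTVolume(img.astype(np.float32), spec.spacing_mm, "HU")


def sample_spec(
    label: int,
    seed: int,
    volume_shape: Tuple[int, int, int] = DEFAULT_VOLUME_SHAPE,
    rng: Optional[np.random.Generator] = None,
) -> PhantomSpec:
    """Draw one class-conditional phantom spec (see module docstring)."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([seed, 2]))
    jitter = tuple(int(n // 2 + rng.integers(-4, 5)) for n in volume_shape)
    if label == 1:
        r0 = rng.uniform(5.0, 15.0)
        a = rng.uniform(0.15, 0.4)
        spikes = int(rng.integers(6, 15))
        hu = rng.uniform(0.0, 100.0)
    else:
        r0 = rng.uniform(1.5, 6.0)
        a = rng.uniform(0.0, 0.1)
        spikes = int(rng.integers(2, 6))
        hu = rng.uniform(-100.0, 0.0)
    return PhantomSpec(
        nodule_radius_mm=r0,
        spiculation_amplitude=a,
        spike_count=spikes,
        label=label,
        seed=seed,
        volume_shape=volume_shape,
        nodule_hu=hu,
        vessel_count=int(rng.integers(2, 6)),
        center_voxel=jitter,
    )


def generate_cohort(
    n: int,
    malignant_fraction: float,
    seed: int,
    out_dir: Path,
    volume_shape: Tuple[int, int, int] = DEFAULT_VOLUME_SHAPE,
) -> pd.DataFrame:
    """Write `n` NIfTI image/mask pairs plus a CSV manifest.

    Deterministic in (n, malignant_fraction, seed). Exactly
    round(n * malignant_fraction) cases are malignant; the label order is
    a seeded shuffle. Returns the manifest with paths relative to out_dir.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if not (0.0 <= malignant_fraction <= 1.0):
        raise ValueError("malignant_fraction must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_mal = int(round(n * malignant_fraction))
    labels = np.array([1] * n_mal + [0] * (n - n_mal))
    np.random.default_rng(np.random.SeedSequence([seed, 3])).shuffle(labels)

    rows = []
    for i, label in enumerate(labels):
        case_seed = int(np.random.SeedSequence([seed, 4, i]).generate_state(1)[0] % (2**31))
        spec = sample_spec(int(label), case_seed, volume_shape)
        mask = make_nodule_mask(spec)
        vol = render_phantom(mask, spec)
        case_id = f"case_{i:04d}"
        img_path, msk_path = f"{case_id}_image.nii.gz", f"{case_id}_mask.nii.gz"
        save_volume(vol, out_dir / img_path)
        save_mask(mask, spec.spacing_mm, out_dir / msk_path)
        cz, cy, cx = spec.center
        rows.append({
            "case_id": case_id, "image_path": img_path, "mask_path": msk_path,
            "label": int(label), "center_z": cz, "center_y": cy, "center_x": cx,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    return manifest


def load_manifest(path: Path) -> pd.DataFrame:
    """Read a cohort manifest, resolving file paths relative to its folder."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    for col in ("image_path", "mask_path"):
        df[col] = df[col].map(
            lambda p: p if Path(p).is_absolute() else str((base / p).resolve())
        )
    return df
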