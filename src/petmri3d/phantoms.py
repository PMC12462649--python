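"""Synthetic dual-channel hot-spot phantoms.

Generates labelled PET/MRI volume pairs with the statistical structure the
classifier assumes in real head-and-neck FDG data:

* a smooth PET background with intensity-proportional noise,
* a high-uptake "brain" analogue occupying the most superior slices (the
  physiological confounder every FDG head-and-neck stack contains),
* in positive cases, one focal ellipsoidal hot-spot of configurable
  contrast, size and depth, always strictly inferior to the brain region,
* an MRI channel built from low-pass-filtered texture under one of several
  contrast archetypes (emulating mixed T1 / fat-suppressed T1 / T2
  acquisitions), carrying only a weak tumour signature by default.

Slice index ``z = 0`` is the most superior transaxial slice. Intensities
are arbitrary units; the preprocessing pipeline min-max scales each volume
anyway, so no SUV calibration is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "VolumeCase",
    "generate_case",
    "generate_dataset",
    "slice_truth",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom population.

    Parameters
    ----------
    shape:
        Voxel grid ``(nx, ny, nz)``; each dimension must be >= 8.
    prevalence:
        Fraction of positive (tumour-bearing) cases in ``[0, 1]``.
    tumour_contrast:
        Ratio of mean tumour intensity to mean PET background intensity
        (>= 1). The brain analogue has its own, independent contrast.
    tumour_radius_range:
        Inclusive ``(min, max)`` ellipsoid semi-axis range in voxels.
    brain_depth_fraction:
        Fraction of the most superior slices occupied by the high-uptake
        brain analogue.
    noise_sd:
        Scale of the intensity-proportional Gaussian noise
        (sd per voxel = ``noise_sd * sqrt(intensity)``).
    mri_contrast_profiles:
        Number of distinct MRI contrast archetypes to draw from,
        emulating a mixed-sequence dataset.
    mri_tumour_contrast:
        Local multiplicative tumour signature in the MRI channel;
        deliberately close to 1 so the anatomical channel is a weaker
        predictor than the metabolic one.
    brain_contrast:
        Ratio of brain-analogue intensity to mean background; kept above
        ``tumour_contrast`` in the defaults so the confounder, not the
        lesion, is the global PET maximum in negative cases.
    voxel_size:
        Physical voxel pitch ``(dx, dy, dz)`` in mm, recorded on cases.
    seed:
        Root seed; fixed seed gives byte-identical output.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    prevalence: float = 0.5
    tumour_contrast: float = 3.0
    tumour_radius_range: tuple[float, float] = (3.0, 6.0)
    brain_depth_fraction: float = 0.25
    noise_sd: float = 0.05
    mri_contrast_profiles: int = 3
    mri_tumour_contrast: float = 2.0
    brain_contrast: float = 5.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if min(nx, ny, nz) < 8:
            raise ValueError(f"shape must be >= 8 per axis, got {self.shape}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.tumour_contrast < 1.0:
            raise ValueError(f"tumour_contrast must be >= 1, got {self.tumour_contrast}")
        lo, hi = self.tumour_radius_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid tumour_radius_range {self.tumour_radius_range}")
        if not 0.0 <= self.brain_depth_fraction < 1.0:
            raise ValueError(
                f"brain_depth_fraction must be in [0, 1), got {self.brain_depth_fraction}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mri_contrast_profiles < 1:
            raise ValueError("mri_contrast_profiles must be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def brain_slices(self) -> int:
        """Number of superior slices occupied by the brain analogue."""
        return math.ceil(self.brain_depth_fraction * self.shape[2])


@dataclass
class VolumeCase:
    """One patient's co-registered dual-channel volume.

    ``pet``, ``mri`` and ``tumour_mask`` (when present) share one spatial
    shape ``(nx, ny, nz)``; co-registration is assumed upstream. ``label``
    is 1 iff the tumour mask has at least one positive voxel when a mask
    is present.
    """

    case_id: str
    pet: np.ndarray
    mri: np.ndarray
    voxel_size: tuple[float, float, float]
    label: int
    tumour_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.pet.ndim != 3 or self.mri.ndim != 3:
            raise ValueError("pet and mri must be 3D arrays")
        if self.pet.shape != self.mri.shape:
            raise ValueError(
                f"channel shapes differ: pet {self.pet.shape} vs mri {self.mri.shape}"
            )
        if self.tumour_mask is not None:
            if self.tumour_mask.shape != self.pet.shape:
                raise ValueError("tumour_mask shape differs from image shape")
            has_tumour = bool(self.tumour_mask.any())
            if has_tumour != bool(self.label):
                raise ValueError(
                    f"label {self.label} inconsistent with mask (any={has_tumour})"
                )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pet.shape


def _ellipsoid_mask(shape, centre, radii) -> np.ndarray:
    nx, ny, nz = shape
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    cx, cy, cz = centre
    rx, ry, rz = radii
    d2 = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    return d2 <= 1.0


def _brain_mask(config: PhantomConfig) -> np.ndarray:
    """In-plane ellipse filling the most superior slices."""
    nx, ny, nz = config.shape
    b = config.brain_slices
    mask = np.zeros(config.shape, dtype=bool)
    if b == 0:
        return mask
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    ellipse = ((x - (nx - 1) / 2) / (0.35 * nx)) ** 2 + (
        (y - (ny - 1) / 2) / (0.35 * ny)
    ) ** 2 <= 1.0
    mask[:, :, :b] = ellipse[:, :, None]
    return mask


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance low-pass random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _mri_archetype(k: int) -> tuple[float, float, float]:
    # (base level, texture contrast, gamma) triples cycling through
    # bright-soft-tissue (T1-like), inverted (T2-like) and
    # high-contrast fat-suppressed looks.
    table = [
        (0.60, 0.25, 1.0),
        (0.35, 0.30, 1.6),
        (0.50, 0.40, 0.7),
        (0.45, 0.20, 1.2),
        (0.55, 0.35, 0.9),
    ]
    return table[k % len(table)]


def generate_case(
    config: PhantomConfig,
    positive: bool,
    rng: np.random.Generator,
    case_id: str = "case",
) -> VolumeCase:
    """Generate one dual-channel phantom.

    The PET channel is a smooth background (mean ~1) plus the brain
    analogue and, for positive cases, one ellipsoidal hot-spot whose mean
    intensity is ``tumour_contrast`` times the mean background. The
    tumour centre depth is uniform over positions where the ellipsoid
    fits strictly below the brain region (it is never forced central).
    Intensity-proportional Gaussian noise is added last.

    Raises
    ------
    ValueError
        If no tumour of the configured radius fits below the brain
        region (names the conflicting fields).
    """
    nx, ny, nz = config.shape
    b = config.brain_slices

    # PET background: level 1 with smooth +-20% structure.
    pet = 1.0 + 0.2 * _smooth_field(rng, config.shape, sigma=4.0)
    pet = np.clip(pet, 0.05, None)

    brain = _brain_mask(config)
    bg_level = float(pet[~brain].mean())
    pet[brain] = config.brain_contrast * bg_level * (
        1.0 + 0.05 * _smooth_field(rng, config.shape, sigma=2.0)[brain]
    )

    mask = np.zeros(config.shape, dtype=np.uint8)
    if positive:
        lo, hi = config.tumour_radius_range
        radii = rng.uniform(lo, hi, size=3)
        rz = radii[2]
        z_min = b + rz
        z_max = nz - 1 - rz
        if z_min > z_max:
            raise ValueError(
                "tumour cannot fit below the brain region: "
                f"brain_depth_fraction={config.brain_depth_fraction} occupies "
                f"{b} of nz={nz} slices but tumour_radius_range="
                f"{config.tumour_radius_range} needs {2 * rz:.1f} slices"
            )
        cz = rng.uniform(z_min, z_max)
        cx = rng.uniform(radii[0], nx - 1 - radii[0])
        cy = rng.uniform(radii[1], ny - 1 - radii[1])
        ell = _ellipsoid_mask(config.shape, (cx, cy, cz), radii)
        ell &= ~brain  # strictly sub-brain by construction of cz
        mask[ell] = 1
        bg = ~brain & ~ell
        pet[ell] = config.tumour_contrast * float(pet[bg].mean())

    # MRI: low-pass texture under one of the contrast archetypes.
    k = int(rng.integers(config.mri_contrast_profiles))
    base, contrast, gamma = _mri_archetype(k)
    texture = _smooth_field(rng, config.shape, sigma=2.0)
    mri = np.clip(base + contrast * texture, 0.02, None) ** gamma
    if positive:
        mri[mask.astype(bool)] *= config.mri_tumour_contrast

    if config.noise_sd > 0:
        pet = pet + rng.normal(0.0, 1.0, config.shape) * (
            config.noise_sd * np.sqrt(np.clip(pet, 0, None))
        )
        mri = mri + rng.normal(0.0, 1.0, config.shape) * (
            config.noise_sd * np.sqrt(np.clip(mri, 0, None))
        )
    pet = np.clip(pet, 0.0, None)
    mri = np.clip(mri, 0.0, None)

    return VolumeCase(
        case_id=case_id,
        pet=pet.astype(np.float32),
        mri=mri.astype(np.float32),
        voxel_size=config.voxel_size,
        label=int(positive),
        tumour_mask=mask,
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def generate_dataset(config: PhantomConfig, n: int) -> list[VolumeCase]:
    """Generate ``n`` phantoms with ``round(n * prevalence)`` positives.

    The positive count rounds half away from zero. Case order is a
    deterministic shuffle of labels under the config seed; case ids are
    unique (``case_0000`` ...). Equal seeds give bit-identical datasets.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    n_pos = round_half_away(n * config.prevalence)
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    ss = np.random.SeedSequence(config.seed)
    order_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    order_rng.shuffle(labels)
    children = np.random.SeedSequence(config.seed).spawn(n + 1)[1:]
    cases = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        cases.append(
            generate_case(config, positive=bool(labels[i]), rng=rng, case_id=f"case_{i:04d}")
        )
    return cases


def slice_truth(case: VolumeCase) -> np.ndarray:
    """Binary per-slice ground truth: 1 iff the tumour mask touches slice z.

    Raises
    ------
    ValueError
        If the case carries no tumour mask.
    """
    if case.tumour_mask is None:
        raise ValueError(f"case {case.case_id} has no tumour mask; slice truth undefined")
    return case.tumour_mask.any(axis=(0, 1)).astype(np.uint8)
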