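"""Volume preprocessing: pitch harmonisation, in-plane resize, depth
windowing, per-volume min-max scaling and 90-degree/flip augmentation.

The training pipeline order is::

    harmonise_voxels -> resize_inplane -> select_depth_window
        -> minmax_scale -> augment

Voxel pitch is harmonised before the in-plane resize so that the final
in-plane grid corresponds to one physical field of view across scanners;
the opposite order (resize first) is available via ``resize_first=True``
on :func:`preprocess_case`. Each step is idempotent where its target
state already holds. Test-time preprocessing skips the depth window:
variable-depth volumes are consumed whole by sliding-window inference.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.ndimage import zoom as nd_zoom
from skimage.transform import resize as sk_resize

from petmri3d.phantoms import VolumeCase

__all__ = [
    "PreprocessConfig",
    "TrainingTensor",
    "harmonise_voxels",
    "resize_inplane",
    "select_depth_window",
    "minmax_scale",
    "augment",
    "preprocess_case",
    "case_rng",
]

Modality = Literal["pet", "mri", "petmri"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    ``target_voxel`` is the pitch every case is resampled to; by
    convention the finest pitch present in the dataset. ``None`` leaves
    pitch untouched (single-scanner data already on one grid).
    """

    inplane_size: int = 64
    depth_window: int = 32
    target_voxel: Optional[tuple[float, float, float]] = None
    interpolation_order: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inplane_size < 8:
            raise ValueError(f"inplane_size must be >= 8, got {self.inplane_size}")
        if self.depth_window < 1:
            raise ValueError(f"depth_window must be >= 1, got {self.depth_window}")
        if self.target_voxel is not None and any(v <= 0 for v in self.target_voxel):
            raise ValueError(f"target_voxel must be positive, got {self.target_voxel}")


@dataclass
class TrainingTensor:
    """A model-ready sample: ``data`` has shape (x, y, z, channel) with
    values in [0, 1]; ``provenance`` records case id and applied
    transforms."""

    data: np.ndarray
    label: int
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, channel), got {self.data.shape}")

    @property
    def case_id(self) -> str:
        return self.provenance[0] if self.provenance else ""


def case_rng(seed: int, case_id: str) -> np.random.Generator:
    """Per-case generator derived from (global seed, case id).

    Stable across runs and process boundaries (unlike ``hash``)."""
    digest = hashlib.sha256(case_id.encode()).digest()
    sub = int.from_bytes(digest[:4], "little")
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, sub])))


def harmonise_voxels(case: VolumeCase, config: PreprocessConfig) -> VolumeCase:
    """Resample both channels onto ``config.target_voxel`` pitch.

    Channels are interpolated at ``interpolation_order`` (default
    trilinear); the mask, when present, is resampled nearest-neighbour so
    it stays binary. A case already at target pitch is returned with
    unchanged geometry.
    """
    if config.target_voxel is None:
        return case
    if any(v <= 0 for v in case.voxel_size):
        raise ValueError(f"non-positive voxel size {case.voxel_size} on {case.case_id}")
    factors = tuple(v / t for v, t in zip(case.voxel_size, config.target_voxel))
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return case
    pet = nd_zoom(case.pet, factors, order=config.interpolation_order, mode="nearest")
    mri = nd_zoom(case.mri, factors, order=config.interpolation_order, mode="nearest")
    mask = None
    if case.tumour_mask is not None:
        mask = nd_zoom(case.tumour_mask, factors, order=0, mode="nearest").astype(np.uint8)
        if mask.any() != bool(case.label):
            # a sub-voxel mask can vanish under coarse resampling; keep
            # the label consistent by preserving the nearest seed voxel
            mask = np.zeros(pet.shape, dtype=np.uint8)
            src = np.argwhere(case.tumour_mask)
            centre = np.round(src.mean(axis=0) * np.array(factors)).astype(int)
            centre = np.clip(centre, 0, np.array(pet.shape) - 1)
            mask[tuple(centre)] = 1
    return VolumeCase(
        case_id=case.case_id,
        pet=pet,
        mri=mri,
        voxel_size=tuple(config.target_voxel),
        label=case.label,
        tumour_mask=mask,
    )


def resize_inplane(case: VolumeCase, config: PreprocessConfig) -> VolumeCase:
    """Resize every transaxial slice to ``inplane_size ** 2`` pixels.

    Downscaling is anti-aliased (area-averaging behaviour: a constant
    slice stays constant); the slice count is unchanged. Upscaling is
    performed but warned about, since it fabricates resolution.
    """
    nx, ny, nz = case.shape
    s = config.inplane_size
    if (nx, ny) == (s, s):
        return case
    if nx < s or ny < s:
        warnings.warn(
            f"upscaling in-plane from {nx}x{ny} to {s}x{s} on {case.case_id}",
            stacklevel=2,
        )
    anti = nx > s or ny > s

    def _resize(vol: np.ndarray, order: int, anti_alias: bool) -> np.ndarray:
        return sk_resize(
            vol,
            (s, s, nz),
            order=order,
            anti_aliasing=anti_alias,
            preserve_range=True,
            mode="edge",
        )

    pet = _resize(case.pet, 1, anti)
    mri = _resize(case.mri, 1, anti)
    mask = None
    if case.tumour_mask is not None:
        mask = _resize(case.tumour_mask.astype(float), 0, False)
        mask = (mask > 0.5).astype(np.uint8)
        if mask.any() != bool(case.label):
            mask = np.zeros(pet.shape, dtype=np.uint8)
            src = np.argwhere(case.tumour_mask)
            centre = src.mean(axis=0) * np.array([s / nx, s / ny, 1.0])
            centre = np.clip(np.round(centre).astype(int), 0, np.array(pet.shape) - 1)
            mask[tuple(centre)] = 1
    # in-plane resize changes the effective pitch proportionally
    dx, dy, dz = case.voxel_size
    voxel = (dx * nx / s, dy * ny / s, dz)
    return VolumeCase(case.case_id, pet, mri, voxel, case.label, mask)


def _centremost_mask_slice(mask: np.ndarray) -> int:
    zs = np.flatnonzero(mask.any(axis=(0, 1)))
    return int(zs[(len(zs) - 1) // 2])


def select_depth_window(
    case: VolumeCase,
    config: PreprocessConfig,
    rng: Optional[np.random.Generator] = None,
) -> VolumeCase:
    """Crop to a contiguous ``depth_window``-slice stack.

    Positive cases: the window extends symmetrically both sides of the
    centremost mask slice and is clamped at the volume boundaries, so the
    tumour is inside the window but not necessarily centred. Negative
    cases: a uniformly random window; when ``rng`` is omitted it is
    derived from ``(config.seed, case_id)`` so the choice is reproducible
    per case.
    """
    nx, ny, nz = case.shape
    w = config.depth_window
    if nz < w:
        raise ValueError(f"volume depth {nz} < depth_window {w} on {case.case_id}")
    if nz == w:
        return case
    if case.label == 1:
        if case.tumour_mask is None or not case.tumour_mask.any():
            raise ValueError(f"positive case {case.case_id} has an empty tumour mask")
        c = _centremost_mask_slice(case.tumour_mask)
        start = min(max(c - w // 2, 0), nz - w)
    else:
        if rng is None:
            rng = case_rng(config.seed, case.case_id)
        start = int(rng.integers(0, nz - w + 1))
    sl = slice(start, start + w)
    mask = case.tumour_mask[:, :, sl] if case.tumour_mask is not None else None
    return VolumeCase(
        case.case_id, case.pet[:, :, sl], case.mri[:, :, sl], case.voxel_size,
        case.label, mask,
    )


def minmax_scale(volume: np.ndarray) -> np.ndarray:
    """Linearly map a volume onto [0, 1] using its own min and max.

    Applied per channel per case. A constant volume maps to all zeros
    (with a warning) rather than raising, so masked or cropped regions
    do not abort a batch.
    """
    vmin = float(volume.min())
    vmax = float(volume.max())
    if vmax == vmin:
        warnings.warn("constant volume: min-max scaling returns zeros", stacklevel=2)
        return np.zeros_like(volume, dtype=np.float32)
    return ((volume - vmin) / (vmax - vmin)).astype(np.float32)


# The eight in-plane symmetries (dihedral group of the square): rotations
# by k*90 degrees, optionally composed with a flip. Identity excluded
# from the augmentation draw.
def _apply_symmetry(data: np.ndarray, k: int, flip: bool) -> np.ndarray:
    out = np.rot90(data, k=k, axes=(0, 1)) if k else data
    if flip:
        out = out[::-1, :, ...]
    return np.ascontiguousarray(out)


_NON_IDENTITY = [(k, f) for f in (False, True) for k in range(4) if (k, f) != (0, False)]


def augment(tensors: Sequence[TrainingTensor], rng: np.random.Generator) -> list[TrainingTensor]:
    """Expand a training set five-fold: originals plus four flipped /
    90-degree-rotated variants per original.

    Rotations are in-plane only, preserving the superior-inferior axis
    that downstream depth-weighted aggregation relies on. Each variant is
    drawn without replacement from the seven non-identity in-plane
    symmetries, so variants of one sample are pairwise distinct and
    labels are preserved.
    """
    if len(tensors) == 0:
        raise ValueError("augment requires a non-empty input")
    out: list[TrainingTensor] = list(tensors)
    for t in tensors:
        picks = rng.choice(len(_NON_IDENTITY), size=4, replace=False)
        for p in picks:
            k, f = _NON_IDENTITY[int(p)]
            out.append(
                TrainingTensor(
                    data=_apply_symmetry(t.data, k, f),
                    label=t.label,
                    provenance=t.provenance + [f"rot90x{k}" + ("+flip" if f else "")],
                )
            )
    return out


def preprocess_case(
    case: VolumeCase,
    config: PreprocessConfig,
    modality: Modality = "petmri",
    crop_depth: bool = True,
    rng: Optional[np.random.Generator] = None,
    resize_first: bool = False,
) -> TrainingTensor:
    """Full per-case pipeline producing a model-ready tensor.

    ``crop_depth=False`` (test-time) keeps the native depth for
    sliding-window inference. ``resize_first=True`` swaps the first two
    steps (in-plane resize before pitch harmonisation).
    """
    steps = [
        lambda c: harmonise_voxels(c, config),
        lambda c: resize_inplane(c, config),
    ]
    if resize_first:
        steps.reverse()
    for step in steps:
        case = step(case)
    log = [case.case_id, f"inplane={config.inplane_size}"]
    if crop_depth:
        case = select_depth_window(case, config, rng=rng)
        log.append(f"depth_window={config.depth_window}")
    channels = {"pet": [case.pet], "mri": [case.mri], "petmri": [case.pet, case.mri]}[modality]
    data = np.stack([minmax_scale(ch) for ch in channels], axis=-1)
    log.append(f"modality={modality};minmax")
    return TrainingTensor(data=data, label=case.label, provenance=log)
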