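"""Grad-CAM heatmaps and per-slice localization profiles.

The heatmap at a convolutional stage is the rectified, channel-weighted
sum of that stage's activations, where each channel's weight is the
spatial mean of the output-probability gradient with respect to the
activation channel. The map is trilinearly upsampled to the input grid
and min-max normalised per volume, so per-slice maxima live on a 0-1
scale comparable across slices of one patient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import zoom as nd_zoom

from petmri3d.inference import SlidingWindowConfig, window_starts
from petmri3d.model import ModelHandle, _to_ncxyz

__all__ = ["Heatmap", "SliceProfile", "gradcam", "gradcam_sliding",
           "slice_profile", "profile_panel"]

DEFAULT_LAYER = "attention2"


@dataclass(frozen=True)
class Heatmap:
    """Non-negative 3D attention map aligned to the input grid,
    min-max normalised per volume (max 1 unless all-zero)."""

    map: np.ndarray
    source_layer: str

    def __post_init__(self) -> None:
        if self.map.ndim != 3:
            raise ValueError("heatmap must be 3D")


def _normalise(m: np.ndarray) -> np.ndarray:
    top = float(m.max())
    return m / top if top > 0 else m


def _raw_cam(model: ModelHandle, tensor: np.ndarray, layer: str) -> np.ndarray:
    """Unnormalised CAM upsampled to the input spatial shape."""
    valid = model.net.STAGE_NAMES
    if layer not in valid:
        raise ValueError(f"unknown layer {layer!r}; valid layers: {list(valid)}")
    x = _to_ncxyz(tensor)
    model.net.forward(x, training=False, keep_activations=True)
    acts = model.net.activation(layer)  # (1, C, x, y, z)
    model.net.zero_grad()
    grads = model.net.backward(np.ones(1, dtype=np.float32), to_stage=layer)
    weights = grads.mean(axis=(2, 3, 4))  # (1, C): spatial mean of dprob/dA
    cam = np.maximum((weights[:, :, None, None, None] * acts).sum(axis=1), 0.0)[0]
    target = x.shape[2:]
    factors = [t / s for t, s in zip(target, cam.shape)]
    up = nd_zoom(cam, factors, order=1, mode="nearest")
    # zoom can be off by one voxel on odd sizes; crop/pad to the target
    up = up[: target[0], : target[1], : target[2]]
    if up.shape != tuple(target):
        pad = [(0, t - s) for t, s in zip(target, up.shape)]
        up = np.pad(up, pad, mode="edge")
    return up


def gradcam(model: ModelHandle, tensor: np.ndarray, layer: str = DEFAULT_LAYER) -> Heatmap:
    """Grad-CAM for one (x, y, z, c) tensor at a convolutional stage
    (default: the final attention block's output)."""
    return Heatmap(map=_normalise(_raw_cam(model, tensor, layer)), source_layer=layer)


def gradcam_sliding(
    model: ModelHandle,
    volume: np.ndarray,
    config: SlidingWindowConfig,
    layer: str = DEFAULT_LAYER,
) -> Heatmap:
    """Grad-CAM over a full-depth volume via the inference windows.

    Each window's unnormalised map is computed independently;
    overlapping windows are merged by voxelwise maximum (preserving the
    max-pixel-per-slice semantics of the profile analysis) and the
    merged map normalised once.
    """
    merged = np.zeros(volume.shape[:3], dtype=float)
    for start in window_starts(volume.shape[2], config):
        sub = volume[:, :, start : start + config.window, :]
        cam = _raw_cam(model, sub, layer)
        sl = slice(start, start + config.window)
        merged[:, :, sl] = np.maximum(merged[:, :, sl], cam)
    return Heatmap(map=_normalise(merged), source_layer=layer)


@dataclass(frozen=True)
class SliceProfile:
    """Per-slice maxima of a normalised heatmap, with optional binary
    per-slice ground truth."""

    values: np.ndarray
    truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.truth is not None and len(self.truth) != len(self.values):
            raise ValueError(
                f"truth length {len(self.truth)} != profile length {len(self.values)}"
            )


def slice_profile(hm: Heatmap, truth: Optional[np.ndarray] = None) -> SliceProfile:
    """Maximum heatmap value per transaxial slice (length nz)."""
    values = hm.map.max(axis=(0, 1))
    if truth is not None:
        truth = np.asarray(truth).astype(np.uint8)
    return SliceProfile(values=values, truth=truth)


def profile_overlap(profile: SliceProfile) -> float:
    """Mean profile value on truth-positive slices minus mean on
    truth-negative slices; NaN when one side is empty (e.g. a false
    positive, where every slice is truth-negative)."""
    if profile.truth is None:
        raise ValueError("profile carries no ground truth")
    t = profile.truth.astype(bool)
    if t.all() or not t.any():
        return math.nan
    return float(profile.values[t].mean() - profile.values[~t].mean())


def profile_panel(profiles: Sequence[SliceProfile]) -> tuple[np.ndarray, list[float]]:
    """Paired-column matrix for a cohort of profiles.

    Returns an ``(nz, 2 * n)`` matrix whose columns alternate binary
    truth and continuous profile per case, plus the per-case overlap
    summary (:func:`profile_overlap`; NaN for all-negative truth).
    Profiles without truth are excluded with a warning.
    """
    kept = [p for p in profiles if p.truth is not None]
    if len(kept) < len(profiles):
        warnings.warn(f"excluded {len(profiles) - len(kept)} profile(s) without ground truth",
                      stacklevel=2)
    if not kept:
        raise ValueError("profile_panel requires at least one profile with truth")
    nz = len(kept[0].values)
    if any(len(p.values) != nz for p in kept):
        raise ValueError("profiles have mismatched slice counts")
    cols = []
    for p in kept:
        cols.append(p.truth.astype(float))
        cols.append(p.values)
    return np.stack(cols, axis=1), [profile_overlap(p) for p in kept]
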