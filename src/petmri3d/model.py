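"""Public model surface: configuration, construction, forward pass,
focal loss and the learning-rate schedule.

The classifier is a residual+attention 3D CNN ending in global average
pooling, a 512-unit dense layer and a single sigmoid output, so one
trained model scores volumes of any depth that survives the two
stride-2 stages (practical minimum ~8 slices).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Union

import numpy as np

from petmri3d.nn.network import Adam, ResidualAttentionNet3D

__all__ = ["ModelConfig", "ModelHandle", "build_model", "forward", "focal_loss",
           "focal_loss_grad", "lr_at", "save_model", "load_model"]

_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation hyper-parameters.

    ``stage_filters`` are the channel counts of the two
    residual+attention stages (64 and 128 by default). ``focal_gamma``
    and ``focal_alpha`` parameterise the focal binary cross-entropy;
    ``lr0``/``decay_rate``/``decay_steps`` the Adam schedule
    ``lr0 * decay_rate ** (step / decay_steps)``.
    """

    in_channels: int = 2
    entry_filters: int | None = None  # None -> stage_filters[0]
    stage_filters: tuple[int, int] = (64, 128)
    dense_units: int = 512
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    lr0: float = 1e-4
    decay_rate: float = 0.96
    decay_steps: int = 100_000
    attention_merge: str = "add"
    bn_in_residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 2):
            raise ValueError(f"in_channels must be 1 or 2, got {self.in_channels}")
        if not self.stage_filters[0] < self.stage_filters[1]:
            raise ValueError(f"stage_filters must be strictly increasing, got {self.stage_filters}")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0 < self.decay_rate <= 1:
            raise ValueError("decay_rate must be in (0, 1]")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not 0 < self.focal_alpha < 1:
            raise ValueError("focal_alpha must be in (0, 1)")

    def fingerprint(self) -> str:
        arch = {k: v for k, v in asdict(self).items()
                if k in ("in_channels", "entry_filters", "stage_filters",
                         "dense_units", "attention_merge", "bn_in_residual")}
        return hashlib.sha256(json.dumps(arch, sort_keys=True, default=list).encode()).hexdigest()[:16]


@dataclass
class ModelHandle:
    """A built (possibly trained) network plus its architecture
    fingerprint and training step counter."""

    net: ResidualAttentionNet3D
    config: ModelConfig
    fingerprint: str
    steps: int = 0


def build_model(config: ModelConfig) -> ModelHandle:
    """Construct the network with seeded He-normal initialisation.

    The same seed yields identical initial parameters.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    net = ResidualAttentionNet3D(
        in_channels=config.in_channels,
        entry_filters=config.entry_filters or config.stage_filters[0],
        stage_filters=tuple(config.stage_filters),
        dense_units=config.dense_units,
        rng=rng,
        attention_merge=config.attention_merge,
        bn_in_residual=config.bn_in_residual,
    )
    return ModelHandle(net=net, config=config, fingerprint=config.fingerprint())


def _to_ncxyz(tensor: np.ndarray) -> np.ndarray:
    """Accept (x, y, z, c) or (n, x, y, z, c); return (n, c, x, y, z)."""
    if tensor.ndim == 4:
        tensor = tensor[None]
    if tensor.ndim != 5:
        raise ValueError(f"expected 4D or 5D input, got shape {tensor.shape}")
    return np.ascontiguousarray(np.moveaxis(tensor, -1, 1), dtype=np.float32)


def forward(model: ModelHandle, tensor: np.ndarray) -> Union[float, np.ndarray]:
    """Inference-mode probability for one sample or a batch.

    ``tensor`` is (x, y, z, channel) or (n, x, y, z, channel); a single
    sample returns a scalar in (0, 1). Batch normalisation uses its
    running statistics, so outputs are independent of batch composition.
    """
    single = tensor.ndim == 4
    probs = model.net.forward(_to_ncxyz(tensor), training=False)
    return float(probs[0]) if single else probs


def focal_loss(prob, label, config: ModelConfig) -> np.ndarray:
    """Focal binary cross-entropy.

    ``-alpha * (1 - p)**gamma * log(p)`` for positives,
    ``-(1 - alpha) * p**gamma * log(1 - p)`` for negatives. With
    ``gamma=0, alpha=0.5`` this is half the standard BCE. Probabilities
    are clipped to ``[1e-7, 1 - 1e-7]``.
    """
    p = np.clip(np.asarray(prob, dtype=np.float64), _EPS, 1 - _EPS)
    y = np.asarray(label, dtype=np.float64)
    a, g = config.focal_alpha, config.focal_gamma
    pos = -a * (1 - p) ** g * np.log(p)
    neg = -(1 - a) * p**g * np.log(1 - p)
    return y * pos + (1 - y) * neg


def focal_loss_grad(prob, label, config: ModelConfig) -> np.ndarray:
    """d(focal loss)/d(prob), matching :func:`focal_loss` exactly."""
    p = np.clip(np.asarray(prob, dtype=np.float64), _EPS, 1 - _EPS)
    y = np.asarray(label, dtype=np.float64)
    a, g = config.focal_alpha, config.focal_gamma
    if g == 0:
        dpos = -a / p
        dneg = (1 - a) / (1 - p)
    else:
        dpos = a * (g * (1 - p) ** (g - 1) * np.log(p) - (1 - p) ** g / p)
        dneg = -(1 - a) * (g * p ** (g - 1) * np.log(1 - p) - p**g / (1 - p))
    return y * dpos + (1 - y) * dneg


def lr_at(step: int, config: ModelConfig) -> float:
    """Learning rate after ``step`` optimiser steps (continuous decay)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return config.lr0 * config.decay_rate ** (step / config.decay_steps)


def make_optimiser(model: ModelHandle) -> Adam:
    c = model.config
    return Adam(model.net, lr0=c.lr0, decay_rate=c.decay_rate, decay_steps=c.decay_steps)


def save_model(model: ModelHandle, path) -> None:
    """Write parameters + architecture fingerprint to an .npz checkpoint."""
    meta = json.dumps({"fingerprint": model.fingerprint,
                       "config": asdict(model.config), "steps": model.steps},
                      default=list)
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.net.state_dict())


def load_model(path) -> ModelHandle:
    """Load a checkpoint, rebuilding the architecture from its own
    recorded config and refusing mismatched state."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["stage_filters"] = tuple(cfg_dict["stage_filters"])
    config = ModelConfig(**cfg_dict)
    if config.fingerprint() != meta["fingerprint"]:
        raise ValueError("checkpoint fingerprint does not match its recorded architecture")
    model = build_model(config)
    model.net.load_state_dict(state)
    model.steps = meta["steps"]
    return model
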