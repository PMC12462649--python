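"""The residual+attention 3D classification network and its optimiser.

Architecture (data flows left to right)::

    entry(conv3 + BN + ReLU, f0)
      -> residual(f0 -> f1, stride 2) -> attention(f1)
      -> residual(f1 -> f2, stride 2) -> attention(f2)
      -> global average pooling -> dense(d, ReLU) -> dense(1) -> sigmoid

A residual block is two conv3+BN(+ReLU) layers with an identity skip
(1x1x1 projection when channel count or stride changes). An attention
block passes its input through two parallel 1x1x1 convolutions that
learn different channel-wise transformations, merges them element-wise
(addition by default, concatenation + 1x1x1 re-projection optionally)
and re-activates with ReLU. Global average pooling makes the head
independent of the spatial input size, so one trained network scores
volumes of varying depth.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from petmri3d.nn.layers import (
    BatchNorm,
    Conv3d,
    Dense,
    Layer,
    ReLU,
    global_avg_pool,
    global_avg_pool_backward,
)

__all__ = ["ResidualAttentionNet3D", "Adam"]


class _EntryBlock:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, use_bn: bool = True):
        self.conv = Conv3d(cin, cout, kernel=3, stride=1, rng=rng)
        self.bn = BatchNorm(cout)
        self.relu = ReLU()
        self.layers = [self.conv, self.bn, self.relu]

    def forward(self, x, training):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, d):
        return self.conv.backward(self.bn.backward(self.relu.backward(d)))


class _ResidualBlock:
    """conv-BN-ReLU, conv-BN, plus (projected) skip, added, re-activated."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator,
                 use_bn: bool = True):
        self.use_bn = use_bn
        self.conv1 = Conv3d(cin, cout, 3, stride, rng)
        self.bn1 = BatchNorm(cout) if use_bn else None
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, 1, rng)
        self.bn2 = BatchNorm(cout) if use_bn else None
        self.project = cin != cout or stride != 1
        if self.project:
            self.proj = Conv3d(cin, cout, 1, stride, rng)
        self.relu_out = ReLU()
        self.layers = [l for l in (
            self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
            self.proj if self.project else None, self.relu_out,
        ) if l is not None]

    def forward(self, x, training):
        h = self.conv1.forward(x, training)
        if self.bn1 is not None:
            h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        if self.bn2 is not None:
            h = self.bn2.forward(h, training)
        skip = self.proj.forward(x, training) if self.project else x
        return self.relu_out.forward(h + skip, training)

    def backward(self, d):
        d = self.relu_out.backward(d)
        dh, dskip = d, d
        if self.bn2 is not None:
            dh = self.bn2.backward(dh)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        if self.bn1 is not None:
            dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        dx = dx + (self.proj.backward(dskip) if self.project else dskip)
        return dx


class _AttentionBlock:
    """Two parallel 1x1x1 channel-mixing convolutions, merged, re-activated."""

    def __init__(self, c: int, rng: np.random.Generator, merge: str = "add"):
        if merge not in ("add", "concat"):
            raise ValueError(f"unknown attention merge {merge!r}")
        self.merge = merge
        self.branch_a = Conv3d(c, c, 1, 1, rng)
        self.branch_b = Conv3d(c, c, 1, 1, rng)
        self.relu = ReLU()
        self.layers = [self.branch_a, self.branch_b, self.relu]
        if merge == "concat":
            self.reproject = Conv3d(2 * c, c, 1, 1, rng)
            self.layers.append(self.reproject)

    def forward(self, x, training):
        a = self.branch_a.forward(x, training)
        b = self.branch_b.forward(x, training)
        if self.merge == "add":
            merged = a + b
        else:
            merged = self.reproject.forward(np.concatenate([a, b], axis=1), training)
            self._c = a.shape[1]
        return self.relu.forward(merged, training)

    def backward(self, d):
        d = self.relu.backward(d)
        if self.merge == "add":
            da, db = d, d
        else:
            dcat = self.reproject.backward(d)
            da, db = dcat[:, : self._c], dcat[:, self._c:]
        return self.branch_a.backward(da) + self.branch_b.backward(db)


class _Head:
    """GAP -> dense(d, ReLU) -> dense(1); returns the pre-sigmoid logit."""

    def __init__(self, cin: int, dense_units: int, rng: np.random.Generator):
        self.fc1 = Dense(cin, dense_units, rng)
        self.relu = ReLU()
        self.fc2 = Dense(dense_units, 1, rng)
        self.layers = [self.fc1, self.relu, self.fc2]

    def forward(self, x, training):
        pooled, self._gap_shape = global_avg_pool(x)
        h = self.relu.forward(self.fc1.forward(pooled, training), training)
        return self.fc2.forward(h, training)[:, 0]

    def backward(self, dlogit):
        d = self.fc2.backward(dlogit[:, None])
        d = self.fc1.backward(self.relu.backward(d))
        return global_avg_pool_backward(d, self._gap_shape)


class ResidualAttentionNet3D:
    """Full network. ``forward`` returns per-sample probabilities.

    ``STAGE_NAMES`` are the inspectable convolutional stages whose
    activations (and activation gradients) Grad-CAM may target.
    """

    STAGE_NAMES = ("entry", "residual1", "attention1", "residual2", "attention2")

    def __init__(
        self,
        in_channels: int,
        entry_filters: int,
        stage_filters: tuple[int, int],
        dense_units: int,
        rng: np.random.Generator,
        attention_merge: str = "add",
        bn_in_residual: bool = True,
    ):
        f1, f2 = stage_filters
        self.blocks = [
            _EntryBlock(in_channels, entry_filters, rng),
            _ResidualBlock(entry_filters, f1, 2, rng, use_bn=bn_in_residual),
            _AttentionBlock(f1, rng, merge=attention_merge),
            _ResidualBlock(f1, f2, 2, rng, use_bn=bn_in_residual),
            _AttentionBlock(f2, rng, merge=attention_merge),
        ]
        self.head = _Head(f2, dense_units, rng)
        self.in_channels = in_channels

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                keep_activations: bool = False) -> np.ndarray:
        """x: (N, C, X, Y, Z) float32 -> probabilities (N,), strictly in (0, 1)."""
        if x.ndim != 5:
            raise ValueError(f"expected 5D (N, C, X, Y, Z) input, got shape {x.shape}")
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"model expects {self.in_channels} channel(s), got {x.shape[1]}"
            )
        h = x.astype(np.float32, copy=False)
        acts = {}
        for name, block in zip(self.STAGE_NAMES, self.blocks):
            h = block.forward(h, training)
            if keep_activations:
                acts[name] = h
        logit = self.head.forward(h, training)
        self._prob = 1.0 / (1.0 + np.exp(-logit))
        # clip away from {0, 1} so the focal loss log terms stay finite
        self._prob = np.clip(self._prob, 1e-7, 1.0 - 1e-7)
        self._acts = acts
        return self._prob

    def backward(self, dprob: np.ndarray, to_stage: str | None = None) -> np.ndarray:
        """Backpropagate d(loss)/d(prob); returns the gradient w.r.t. the
        activations of ``to_stage`` (or the input when None)."""
        dlogit = dprob * self._prob * (1.0 - self._prob)
        d = self.head.backward(dlogit)
        stop = -1 if to_stage is None else self.STAGE_NAMES.index(to_stage)
        for i in range(len(self.blocks) - 1, stop, -1):
            d = self.blocks[i].backward(d)
        return d

    def activation(self, stage: str) -> np.ndarray:
        if stage not in self._acts:
            raise KeyError(
                f"unknown or un-kept stage {stage!r}; valid stages: {self.STAGE_NAMES}"
            )
        return self._acts[stage]

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> Iterator[tuple[str, Layer]]:
        for bname, block in zip(self.STAGE_NAMES, self.blocks):
            for i, layer in enumerate(block.layers):
                if layer.params:
                    yield f"{bname}.{i}", layer
        for i, layer in enumerate(self.head.layers):
            if layer.params:
                yield f"head.{i}", layer

    def zero_grad(self) -> None:
        for _, layer in self._layers():
            layer.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for lname, layer in self._layers():
            for k, v in layer.params.items():
                state[f"{lname}.{k}"] = v.copy()
            if isinstance(layer, BatchNorm):
                state[f"{lname}.running_mean"] = layer.running_mean.copy()
                state[f"{lname}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for lname, layer in self._layers():
            for k in layer.params:
                layer.params[k][...] = state[f"{lname}.{k}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"{lname}.running_mean"]
                layer.running_var[...] = state[f"{lname}.running_var"]

    def n_parameters(self) -> int:
        return sum(v.size for _, layer in self._layers() for v in layer.params.values())


class Adam:
    """Adam with continuous exponential learning-rate decay:
    ``lr(step) = lr0 * decay_rate ** (step / decay_steps)``."""

    def __init__(self, net: ResidualAttentionNet3D, lr0: float = 1e-4,
                 decay_rate: float = 0.96, decay_steps: int = 100_000,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr0, self.decay_rate, self.decay_steps = lr0, decay_rate, decay_steps
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.step_count = 0
        self._m = {key: np.zeros_like(layer.params[k])
                   for lname, layer in net._layers()
                   for k in layer.params
                   for key in [f"{lname}.{k}"]}
        self._v = {k: np.zeros_like(v) for k, v in self._m.items()}

    def lr_at(self, step: int) -> float:
        return self.lr0 * self.decay_rate ** (step / self.decay_steps)

    def step(self) -> None:
        self.step_count += 1
        lr = self.lr_at(self.step_count)
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.step_count
        bc2 = 1 - b2**self.step_count
        for lname, layer in self.net._layers():
            for k, p in layer.params.items():
                key = f"{lname}.{k}"
                g = layer.grads[k]
                self._m[key] = b1 * self._m[key] + (1 - b1) * g
                self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
                mhat = self._m[key] / bc1
                vhat = self._v[key] / bc2
                p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
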