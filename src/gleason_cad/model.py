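"""The three-scale pyramidal patch CNN.

Each pyramid level (input sides 100, 150, 200) uses the same
architecture: four blocks of (3x3 valid convolution -> 2x2 max-pool ->
dropout) with 16/32/64/128 filters, then fully connected layers of 64
and 512 units (dropout 0.15 after each), then a 5-way softmax over the
Gleason patterns GP1..GP5.  Valid convolutions and floor-division
pooling give final feature-map sides 4, 7 and 10 for the three input
sides, and trainable-parameter totals of 264,421 / 534,757 / 952,549
with no non-trainable parameters — the architecture's fingerprint,
asserted in the test suite.

The network is implemented as a small NumPy layer stack (NHWC float32
tensors, im2col convolutions); see :mod:`gleason_cad.training` for the
optimizer and training loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

CONV_FILTERS = (16, 32, 64, 128)
CONV_DROPOUT = (0.1, 0.1, 0.3, 0.3)
FC_UNITS = (64, 512)
FC_DROPOUT = (0.15, 0.15)
N_CLASSES = 5
KERNEL = 3


# ---------------------------------------------------------------------------
# Architecture description and closed-form parameter count
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of one pyramid level's CNN."""

    input_side: int
    conv_filters: tuple[int, ...] = CONV_FILTERS
    kernel: int = KERNEL
    conv_dropout: tuple[float, ...] = CONV_DROPOUT
    fc_units: tuple[int, ...] = FC_UNITS
    fc_dropout: tuple[float, ...] = FC_DROPOUT
    classes: int = N_CLASSES

    def feature_sides(self) -> list[int]:
        """Spatial side after each conv+pool block: side -> (side-2)//2."""
        sides = []
        side = self.input_side
        for _ in self.conv_filters:
            side = (side - self.kernel + 1) // 2
            sides.append(side)
        return sides

    @property
    def feature_side(self) -> int:
        return self.feature_sides()[-1]

    @property
    def flatten_units(self) -> int:
        return self.conv_filters[-1] * self.feature_side ** 2

    def count_parameters(self) -> int:
        """Closed-form trainable-parameter count (weights + biases)."""
        total = 0
        c_in = 3
        for f in self.conv_filters:
            total += (self.kernel * self.kernel * c_in + 1) * f
            c_in = f
        n_in = self.flatten_units
        for units in self.fc_units:
            total += (n_in + 1) * units
            n_in = units
        total += (n_in + 1) * self.classes
        return total

    @property
    def non_trainable_parameters(self) -> int:
        return 0  # no batch-norm or other frozen state anywhere

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv2D:
    """3x3 valid cross-correlation, stride 1, NHWC."""

    def __init__(self, in_channels: int, filters: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (KERNEL * KERNEL * in_channels))
        self.w = rng.normal(0.0, scale, (KERNEL, KERNEL, in_channels, filters)).astype(
            np.float32
        )
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._cols = sliding_window_view(x, (KERNEL, KERNEL), axis=(1, 2))
        return (
            np.tensordot(self._cols, self.w, axes=([3, 4, 5], [2, 0, 1])) + self.b
        ).astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        # (C,k,k,F) -> (k,k,C,F)
        self.dw = np.tensordot(
            self._cols, g, axes=([0, 1, 2], [0, 1, 2])
        ).transpose(1, 2, 0, 3).astype(np.float32)
        self.db = g.sum(axis=(0, 1, 2)).astype(np.float32)
        pad = KERNEL - 1
        gp = np.pad(g, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        gcols = sliding_window_view(gp, (KERNEL, KERNEL), axis=(1, 2))
        w_flip = self.w[::-1, ::-1]
        return np.tensordot(gcols, w_flip, axes=([3, 4, 5], [3, 0, 1])).astype(
            np.float32
        )

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _ReLU:
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class _MaxPool2:
    """2x2 max-pool, stride 2, floor division (trailing row/col dropped)."""

    def forward(self, x, train, rng):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : 2 * h2, : 2 * w2, :]
        # (B, h2, w2, C, 4) with the 2x2 window flattened last
        xt = xc.reshape(b, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        self._windows_shape = xt.shape
        flat = xt.reshape(b, h2, w2, c, 4)
        self._argmax = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, g):
        b, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        flat = np.zeros((b, h2, w2, c, 4), dtype=g.dtype)
        np.put_along_axis(flat, self._argmax[..., None], g[..., None], axis=-1)
        xt = flat.reshape(self._windows_shape).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape, dtype=g.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = xt.reshape(b, 2 * h2, 2 * w2, c)
        return dx

    def params(self):
        return []


class _Dropout:
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.dw = (self._x.T @ g).astype(np.float32)
        self.db = g.sum(axis=0).astype(np.float32)
        return g @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


# ---------------------------------------------------------------------------
# The realized network
# ---------------------------------------------------------------------------

class PatchCNN:
    """Realized trainable network for one pyramid level."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_in = 3
        for filters, rate in zip(spec.conv_filters, spec.conv_dropout):
            self.layers += [
                _Conv2D(c_in, filters, rng),
                _ReLU(),
                _MaxPool2(),
                _Dropout(rate),
            ]
            c_in = filters
        self.layers.append(_Flatten())
        n_in = spec.flatten_units
        for units, rate in zip(spec.fc_units, spec.fc_dropout):
            self.layers += [_Dense(n_in, units, rng), _ReLU(), _Dropout(rate)]
            n_in = units
        self.layers.append(_Dense(n_in, spec.classes, rng))
        self._rng = np.random.default_rng(seed + 1)  # dropout stream

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Logits for a batch of N x N x 3 patches scaled to [0, 1]."""
        if x.ndim != 4 or x.shape[1:3] != (self.spec.input_side,) * 2:
            raise ValueError(
                f"expected batch of {self.spec.input_side}x{self.spec.input_side} "
                f"patches, got {x.shape}"
            )
        rng = rng if rng is not None else self._rng
        out = x.astype(np.float32, copy=False)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class probabilities (softmax over the 5 GPs), in eval mode."""
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(probs, axis=0)

    # -- parameter bookkeeping ---------------------------------------------

    def parameters(self):
        """List of (array, gradient) pairs across all layers."""
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    @property
    def n_parameters(self) -> int:
        """Trainable-parameter count as reported by the realized layers."""
        return sum(p.size for p, _ in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.parameters(), weights):
            p[...] = w

    def save(self, path) -> None:
        np.savez(path, *[p for p, _ in self.parameters()])

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_network(input_side: int, seed: int = 0) -> PatchCNN:
    """Build the CNN for one pyramid level.

    The four valid-conv + pool blocks shrink the spatial side by
    ``side -> (side - 2) // 2``; inputs too small to leave a >= 1 px
    feature map are rejected.
    """
    spec = NetworkSpec(input_side=input_side)
    if spec.feature_side < 1:
        raise ValueError("input too small for architecture")
    return PatchCNN(spec, seed=seed)


def count_parameters(spec: NetworkSpec) -> int:
    """Closed-form trainable-parameter count for ``spec``."""
    return spec.count_parameters()
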