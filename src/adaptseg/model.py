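"""The 3D U-Net used by all deep-learning regimes.

Four down/upsampling levels, instance normalization, ReLU activations, max
pooling (kernel 2, stride 2) on the way down and transposed convolution
(kernel 2, stride 2) with skip concatenation on the way up; a final 1x1x1
convolution produces one logit channel per structure. Output channels are
*independent* per-structure probabilities (sigmoid), because anatomical
structures may overlap and labels can be missing per structure — a softmax
would force mutual exclusivity the data violates.

Channel configurations: the reference and patient-specific regimes take
only the mid-treatment image (C = 1); the general adaptive regime takes the
mid-treatment image, the aligned pre-treatment image and the S pre-treatment
label channels (C = 2 + S) — for the 17-structure head-and-neck set that is
19 input channels. Channel order is fixed: mid image, pre image, then labels
in cohort structure order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .unet_ops import ConvBlock, MaxPool, OutConv, UpConv

__all__ = ["ModelSpec", "UNet3D", "build_model", "predict", "sigmoid"]


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    ``in_channels`` is 1 for image-only regimes and ``2 + out_channels`` for
    the prior-conditioned regime. ``base_width`` is the channel width of the
    first encoder level (doubled per level); the desk-scale default is 8.
    """

    in_channels: int
    out_channels: int
    base_width: int = 8
    depth: int = 4
    norm: str = "instance"
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1 or self.base_width < 1:
            raise ValueError("channel counts and base width must be >= 1")
        if self.norm != "instance" or self.activation != "relu":
            raise ValueError("only instance norm + ReLU are supported")

    @classmethod
    def for_regime(cls, regime: str, n_structures: int, base_width: int = 8) -> "ModelSpec":
        regime = regime.upper()
        if regime in ("RM", "PSM"):
            c = 1
        elif regime == "GAM":
            c = 2 + n_structures
        else:
            raise ValueError(f"unknown regime {regime!r}")
        return cls(c, n_structures, base_width=base_width)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class UNet3D:
    """Plain-numpy/numba 3D U-Net with explicit forward/backward passes.

    ``forward`` returns logits; :meth:`predict_proba` applies the sigmoid.
    The input's spatial dimensions must be divisible by ``2 ** depth``.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        w = spec.base_width
        self.enc: list[tuple[ConvBlock, ConvBlock]] = []
        self.pools: list[MaxPool] = []
        c_prev = spec.in_channels
        for level in range(spec.depth):
            c = w * 2 ** level
            self.enc.append((ConvBlock(c_prev, c, rng, dtype=dtype), ConvBlock(c, c, rng, dtype=dtype)))
            self.pools.append(MaxPool())
            c_prev = c
        c_bot = w * 2 ** spec.depth
        self.bottleneck = (ConvBlock(c_prev, c_bot, rng, dtype=dtype), ConvBlock(c_bot, c_bot, rng, dtype=dtype))
        self.ups: list[UpConv] = []
        self.dec: list[tuple[ConvBlock, ConvBlock]] = []
        c_prev = c_bot
        for level in reversed(range(spec.depth)):
            c = w * 2 ** level
            self.ups.append(UpConv(c_prev, c, rng, dtype=dtype))
            self.dec.append((ConvBlock(2 * c, c, rng, dtype=dtype), ConvBlock(c, c, rng, dtype=dtype)))
            c_prev = c
        self.out = OutConv(c_prev, spec.out_channels, rng, dtype=dtype)

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list:
        out = []
        for a, b in self.enc:
            out += [a, b]
        out += [a for a in self.pools]
        out += list(self.bottleneck)
        out += list(self.ups)
        for a, b in self.dec:
            out += [a, b]
        out.append(self.out)
        return out

    def parameter_count(self) -> int:
        return int(sum(p.size for layer in self.layers() for p, _ in layer.params()))

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.spec.in_channels:
            raise ValueError(
                f"expected input of shape ({self.spec.in_channels}, D, H, W), got {x.shape}"
            )
        f = 2 ** self.spec.depth
        bad = [d for d in x.shape[1:] if d % f]
        if bad:
            pad = [int(np.ceil(d / f) * f) for d in x.shape[1:]]
            raise ValueError(
                f"spatial dimensions {x.shape[1:]} must be divisible by {f} "
                f"for {self.spec.depth} pooling levels; pad to {tuple(pad)}"
            )

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_input(x)
        h = np.ascontiguousarray(x, dtype=self.dtype)
        self._skips = []
        for (c1, c2), pool in zip(self.enc, self.pools):
            h = c2.forward(c1.forward(h))
            self._skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck[1].forward(self.bottleneck[0].forward(h))
        for up, (c1, c2) in zip(self.ups, self.dec):
            h = up.forward(h)
            skip = self._skips.pop()
            self._cat_channels = skip.shape[0]
            h = np.concatenate([skip, h], axis=0)
            h = c2.forward(c1.forward(h))
        return self.out.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dlogits (no input gradient)."""
        d = self.out.backward(dlogits)
        skip_grads = []
        for up, (c1, c2) in zip(reversed(self.ups), reversed(self.dec)):
            d = c1.backward(c2.backward(d))
            c = d.shape[0] // 2
            skip_grads.append(d[:c])
            d = up.backward(d[c:])
        d = self.bottleneck[0].backward(self.bottleneck[1].backward(d))
        for (c1, c2), pool in zip(reversed(self.enc), reversed(self.pools)):
            d = pool.backward(d) + skip_grads.pop()
            # the very first conv block needs no input gradient
            d = c1.backward(c2.backward(d), need_dx=(c1 is not self.enc[0][0]))
        self._skips = []

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x))

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p, _ in layer.params()]

    def save(self, path: str | Path) -> None:
        """Weights as .npz with a JSON architecture sidecar for validation."""
        path = Path(path)
        np.savez_compressed(path, *self.state_arrays())
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(asdict(self.spec), fh)

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "UNet3D":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            spec = ModelSpec(**json.load(fh))
        model = cls(spec, seed=seed)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
            arrays = [data[k] for k in data.files]
        targets = model.state_arrays()
        if len(arrays) != len(targets):
            raise ValueError("weight file does not match the architecture sidecar")
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError("weight shapes do not match the architecture sidecar")
            dst[...] = src
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> UNet3D:
    """Construct the U-Net for a :class:`ModelSpec` (thin functional wrapper)."""
    return UNet3D(spec, seed=seed)


def predict(model: UNet3D, x: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Per-channel independent probabilities; thresholded masks if requested."""
    p = model.predict_proba(x)
    if threshold is None:
        return p
    return p >= threshold
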