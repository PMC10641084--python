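"""Encoder–decoder reconstruction network on the numpy autodiff engine.

The deconvolution network is a compact U-style encoder–decoder: two 3×3
conv+ReLU layers per resolution level, 2× average-pool downsampling, nearest
upsampling with skip concatenation, and a final 1×1 projection added to the
input (global residual). The residual head is zero-initialized, so a freshly
built network is exactly the identity map — a sensible starting point for a
restoration problem and convenient for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["NetworkDescriptor", "NetworkWeights", "build_network",
           "network_forward", "apply_network", "save_weights", "load_weights"]


@dataclass(frozen=True)
class NetworkDescriptor:
    """Architecture descriptor; fully determines every parameter shape."""

    depth: int = 3
    base_channels: int = 16
    in_channels: int = 1
    input_size: int | None = None  # optional divisibility contract

    def validate_input(self, h: int, w: int) -> None:
        div = 2 ** self.depth
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2^depth = {div}"
            )


@dataclass
class NetworkWeights:
    """Trainable parameters plus the descriptor that shaped them."""

    descriptor: NetworkDescriptor
    params: dict[str, np.ndarray]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.descriptor,
                              {k: v.copy() for k, v in self.params.items()})


def _he(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


def build_network(descriptor: NetworkDescriptor, seed: int = 0,
                  dtype=np.float32) -> NetworkWeights:
    """Deterministically initialize a network for the given descriptor."""
    rng = np.random.default_rng(seed)
    d, c0, cin = descriptor.depth, descriptor.base_channels, descriptor.in_channels
    params: dict[str, np.ndarray] = {}

    def conv(name, cout, cin_):
        params[f"{name}.w"] = _he(rng, (cout, cin_, 3, 3), dtype)
        params[f"{name}.b"] = np.zeros(cout, dtype=dtype)

    ch = cin
    enc_channels = []
    for lvl in range(d + 1):  # last level is the bottleneck
        cout = c0 * 2 ** lvl
        conv(f"enc{lvl}a", cout, ch)
        conv(f"enc{lvl}b", cout, cout)
        enc_channels.append(cout)
        ch = cout
    for lvl in range(d - 1, -1, -1):
        skip = enc_channels[lvl]
        conv(f"dec{lvl}a", skip, ch + skip)
        conv(f"dec{lvl}b", skip, skip)
        ch = skip
    # zero-initialized residual head: fresh network == identity
    params["head.w"] = np.zeros((cin, ch, 1, 1), dtype=dtype)
    params["head.b"] = np.zeros(cin, dtype=dtype)
    return NetworkWeights(descriptor, params)


def network_forward(x: Tensor, weights: NetworkWeights,
                    param_tensors: dict[str, Tensor] | None = None) -> Tensor:
    """Run the network on a (B, C, H, W) tensor.

    ``param_tensors`` lets a training loop supply parameter Tensors that
    require gradients; otherwise constants are created from the stored
    arrays.
    """
    desc = weights.descriptor
    bsz, c, h, w = x.data.shape
    desc.validate_input(h, w)
    if param_tensors is None:
        param_tensors = {k: Tensor(v) for k, v in weights.params.items()}
    p = param_tensors

    def block(t, name):
        t = ad.relu(ad.conv2d(t, p[f"{name}a.w"], p[f"{name}a.b"]))
        t = ad.relu(ad.conv2d(t, p[f"{name}b.w"], p[f"{name}b.b"]))
        return t

    skips = []
    t = x
    for lvl in range(desc.depth):
        t = block(t, f"enc{lvl}")
        skips.append(t)
        t = ad.avg_pool2(t)
    t = block(t, f"enc{desc.depth}")
    for lvl in range(desc.depth - 1, -1, -1):
        t = ad.upsample2(t)
        t = ad.concat(t, skips[lvl])
        t = block(t, f"dec{lvl}")
    residual = ad.conv2d(t, p["head.w"], p["head.b"])
    return x + residual


def apply_network(image: np.ndarray, weights: NetworkWeights) -> np.ndarray:
    """Inference on a single 2-D image (no gradients)."""
    dtype = next(iter(weights.params.values())).dtype
    x = Tensor(np.asarray(image, dtype=dtype)[None, None])
    out = network_forward(x, weights)
    return out.data[0, 0].astype(float)


# ---------------------------------------------------------------------------
# serialization


def save_weights(weights: NetworkWeights, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "depth": weights.descriptor.depth,
        "base_channels": weights.descriptor.base_channels,
        "in_channels": weights.descriptor.in_channels,
        "input_size": weights.descriptor.input_size,
    }
    np.savez(path, __descriptor__=json.dumps(meta), **weights.params)


def load_weights(path: str | Path) -> NetworkWeights:
    with np.load(path, allow_pickle=False) as blob:
        meta = json.loads(str(blob["__descriptor__"]))
        params = {k: blob[k] for k in blob.files if k != "__descriptor__"}
    return NetworkWeights(NetworkDescriptor(**meta), params)
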