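"""The shared segmentation backbone f(x; θ): a 4-level U-Net for 2D and 3D.

Contracting path: four blocks, each two same-padded convolutions (kernel 3
per axis) with an intermediate dropout layer, leaky-ReLU (slope 0.1) after
every convolution, and factor-2 average pooling after each block.  A
lowest-resolution block of the same form bridges into the expanding path
(four pooling steps, hence input extents must be divisible by 16).
Expanding path: four blocks, each preceded by factor-2 linear upsampling
and concatenation of the matching contracting features.  A final 1x1(x1)
convolution maps to ``num_classes`` channels followed by a voxel-wise
softmax.  No normalization layers are used.  Weights follow He-style
initialization.

Parameters live in a flat ``{name: ndarray}`` dict so that scalar-linear
combinations (the EMA teacher update) and checkpointing are trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .io_preprocess import ImageSample

__all__ = ["ModelParams", "build_unet", "forward", "predict",
           "save_checkpoint", "load_checkpoint", "parameter_count"]

POOL_STEPS = 4
DIVISIBILITY = 2 ** POOL_STEPS


@dataclass
class ModelParams:
    """Named weight tensors plus the architecture metadata to rebuild f."""

    params: Dict[str, np.ndarray]
    dim: int
    num_classes: int
    base_channels: int = 64
    dropout_rate: float = 0.1
    seed: int = 0
    iteration: int = 0

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.params.items()},
                           self.dim, self.num_classes, self.base_channels,
                           self.dropout_rate, self.seed, self.iteration)

    def linear_combination(self, other: "ModelParams", alpha: float) -> "ModelParams":
        """alpha * self + (1 - alpha) * other, elementwise over θ."""
        out = {k: alpha * v + (1.0 - alpha) * other.params[k]
               for k, v in self.params.items()}
        return ModelParams(out, self.dim, self.num_classes, self.base_channels,
                           self.dropout_rate, self.seed, self.iteration)


def _he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int,
             dim: int) -> np.ndarray:
    fan_in = c_in * k ** dim
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                   size=(c_out, c_in) + (k,) * dim)
    return w.astype(np.float32)


def _block_names(name: str):
    return (f"{name}.conv1.w", f"{name}.conv1.b",
            f"{name}.conv2.w", f"{name}.conv2.b")


def build_unet(dim: int, num_classes: int, seed: int,
               base_channels: int = 64, dropout_rate: float = 0.1) -> ModelParams:
    """Initialize θ for the backbone; identical seeds give identical θ."""
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    rng = np.random.default_rng(seed)
    c = base_channels
    params: Dict[str, np.ndarray] = {}

    def add_block(name: str, c_in: int):
        w1, b1, w2, b2 = _block_names(name)
        params[w1] = _he_conv(rng, c, c_in, 3, dim)
        params[b1] = np.zeros(c, dtype=np.float32)
        params[w2] = _he_conv(rng, c, c, 3, dim)
        params[b2] = np.zeros(c, dtype=np.float32)

    add_block("enc1", 1)
    for lvl in range(2, POOL_STEPS + 1):
        add_block(f"enc{lvl}", c)
    add_block("bottom", c)
    for lvl in range(POOL_STEPS, 0, -1):
        add_block(f"dec{lvl}", 2 * c)          # upsampled + skip concat
    # the 1x1 classification head starts at a tenth of the He scale so the
    # initial softmax is near-uniform: a strongly asymmetric start lets the
    # volume-weighted Dice loss suppress small classes past the point of
    # recovery (softmax saturation) before their features have formed
    params["head.w"] = 0.1 * _he_conv(rng, num_classes, c, 1, dim)
    params["head.b"] = np.zeros(num_classes, dtype=np.float32)
    return ModelParams(params, dim, num_classes, base_channels, dropout_rate,
                       seed)


def parameter_count(m: ModelParams) -> int:
    return int(sum(v.size for v in m.params.values()))


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _check_extent(shape: Tuple[int, ...], dim: int) -> None:
    if len(shape) != dim:
        raise ValueError(f"expected {dim}D input, got shape {shape}")
    if any(s % DIVISIBILITY for s in shape):
        raise ValueError(
            f"input extent {shape} must be divisible by {DIVISIBILITY}")


def forward(m: ModelParams, x: np.ndarray, training: bool = False,
            rng: Optional[np.random.Generator] = None,
            requires_grad: bool = False, leaves=None):
    """Run f(x; θ) on a single image.

    Returns ``(probs, leaves)`` where ``probs`` is the softmax output
    Tensor of shape (num_classes, *grid) and ``leaves`` maps parameter
    names to their leaf Tensors (whose ``.grad`` is filled by backward).
    Passing the ``leaves`` of a previous call re-uses those leaf Tensors,
    so gradients from several forward passes in one loss accumulate into
    a single set.  Dropout is active only with ``training=True``; ``rng``
    then drives the masks.
    """
    x = np.asarray(x, dtype=np.float32)
    _check_extent(x.shape, m.dim)
    if training and rng is None:
        raise ValueError("training mode needs an rng for dropout")
    rate = m.dropout_rate if training else 0.0
    if leaves is None:
        leaves = {k: ad.Tensor(v, requires_grad=requires_grad)
                  for k, v in m.params.items()}

    def block(name: str, t: ad.Tensor) -> ad.Tensor:
        w1, b1, w2, b2 = _block_names(name)
        t = ad.leaky_relu(ad.conv_nd(t, leaves[w1], leaves[b1]), 0.1)
        if rate > 0.0:
            t = ad.dropout(t, rate, rng)
        return ad.leaky_relu(ad.conv_nd(t, leaves[w2], leaves[b2]), 0.1)

    t = ad.Tensor(x[None])                    # (1, *grid) channel axis
    skips = []
    for lvl in range(1, POOL_STEPS + 1):
        t = block(f"enc{lvl}", t)
        skips.append(t)
        t = ad.avg_pool(t, 2)
    t = block("bottom", t)
    for lvl in range(POOL_STEPS, 0, -1):
        t = ad.upsample_linear(t, 2)
        t = ad.concat([t, skips[lvl - 1]], axis=0)
        t = block(f"dec{lvl}", t)
    logits = ad.conv_nd(t, leaves["head.w"], leaves["head.b"])
    return ad.softmax(logits, axis=0), leaves


def predict(m: ModelParams, img, training: bool = False,
            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Probability map (num_classes, *grid) as a plain array (no tape)."""
    x = img.pixels if isinstance(img, ImageSample) else img
    probs, _ = forward(m, x, training=training, rng=rng, requires_grad=False)
    return probs.data


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(m: ModelParams, path) -> Path:
    """Named-tensor archive (.npz) plus a JSON manifest alongside."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez(path, **m.params)
    manifest = {"dim": m.dim, "num_classes": m.num_classes,
                "base_channels": m.base_channels,
                "dropout_rate": m.dropout_rate, "seed": m.seed,
                "iteration": m.iteration}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path


def load_checkpoint(path) -> ModelParams:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        params = {k: data[k] for k in data.files}
    return ModelParams(params, manifest["dim"], manifest["num_classes"],
                       manifest["base_channels"], manifest["dropout_rate"],
                       manifest["seed"], manifest.get("iteration", 0))
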