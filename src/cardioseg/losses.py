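"""Supervised generalized Dice loss, consistency MSE, and total-loss composition.

The generalized Dice loss (GDL) weights every class, background included,
by the squared reciprocal of its target volume, so small structures count
as much as large ones.  Consistency targets (warped predictions, teacher
outputs, anything on the target side of an unsupervised term) are treated
as constants: they are detached from the autodiff tape before entering the
loss, so no gradient ever flows through a target branch.

Four total losses are composed from the parts:

====================  =============================================
variant               total loss
====================  =============================================
``TC``                LSV + λ · LTC
``ST``                LSV + λ · LST
``PL``                LSV + λ1 · LPL
``CASCADE``           LSV + λ1 · LPL + λ2 · LST
====================  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .io_preprocess import LabelMap

__all__ = ["LossWeights", "generalized_dice_loss", "consistency_mse",
           "compose_total_loss", "VARIANT_PARTS"]

_EPS = 1e-8


@dataclass
class LossWeights:
    """λ (consistency), λ1 (pseudo-label), λ2 (cascade consistency)."""

    lambda_tc_or_st: float = 10.0
    lambda_pl: float = 1.0
    lambda_st_cascade: float = 10.0

    def __post_init__(self):
        if min(self.lambda_tc_or_st, self.lambda_pl,
               self.lambda_st_cascade) < 0:
            raise ValueError("loss weights must be non-negative")


def _as_one_hot(target, num_classes: int, spatial_shape, dtype):
    if isinstance(target, LabelMap):
        if target.shape != spatial_shape:
            raise ValueError("prediction and target grids differ")
        return target.one_hot(dtype=dtype)
    t = np.asarray(target)
    if t.shape != (num_classes,) + spatial_shape:
        raise ValueError("prediction and target grids differ")
    return t.astype(dtype)


def generalized_dice_loss(pred, target) -> Tensor:
    """1 - GDS with Sudre-style class weights w_c = 1 / (Σ_v t_cv)².

    ``pred`` is a (C, *grid) probability map (Tensor or array); ``target``
    a :class:`LabelMap` or a one-hot array on the same grid.  Classes
    absent from the target are kept in the sums with the largest finite
    class weight rather than dropped.  The value lies in [0, 1]: 0 for
    perfect overlap, 1 for fully disjoint foregrounds.
    """
    pred = as_tensor(pred)
    num_classes = pred.shape[0]
    spatial = tuple(pred.shape[1:])
    t = _as_one_hot(target, num_classes, spatial, pred.data.dtype)
    spatial_axes = tuple(range(1, t.ndim))
    volumes = t.sum(axis=spatial_axes).astype(np.float64)
    # squared-reciprocal-volume class weights; a class absent from the
    # target would get infinite weight and swamp the loss, so it receives
    # the largest finite (i.e. smallest present class) weight instead
    with np.errstate(divide="ignore"):
        w = 1.0 / volumes ** 2
    finite = np.isfinite(w)
    if not finite.all():
        w[~finite] = w[finite].max() if finite.any() else 1.0
    w = w.astype(pred.data.dtype)
    w_full = w.reshape((num_classes,) + (1,) * len(spatial))
    intersect = (pred * (w_full * t)).sum()
    denom = ((pred + t) * w_full).sum()
    return 1.0 - 2.0 * intersect / denom


def consistency_mse(pred, target) -> Tensor:
    """Mean over voxels and channels of squared differences.

    The target is detached (stop-gradient) by contract: consistency targets
    act as constants during back-propagation.
    """
    pred = as_tensor(pred)
    target = as_tensor(target).detach()
    if pred.shape != target.shape:
        raise ValueError("prediction and target grids differ")
    diff = pred - target
    return (diff * diff).mean()


VARIANT_PARTS = {
    "TC": ("lsv", "ltc"),
    "ST": ("lsv", "lst"),
    "PL": ("lsv", "lpl"),
    "CASCADE": ("lsv", "lpl", "lst"),
}


def compose_total_loss(variant: str, parts: dict, w: LossWeights):
    """Weighted sum of the named loss parts for one training variant.

    ``parts`` must supply exactly the terms the variant needs (keys per
    :data:`VARIANT_PARTS`); scalars and Tensors both work.  Gradients flow
    only through the prediction-side terms because each part's target was
    detached when the part was computed.
    """
    variant = variant.upper()
    if variant not in VARIANT_PARTS:
        raise ValueError(f"unknown variant {variant!r}")
    needed = VARIANT_PARTS[variant]
    if set(parts) != set(needed):
        raise ValueError(
            f"variant {variant} needs parts {sorted(needed)}, got {sorted(parts)}")
    total = parts["lsv"]
    if variant == "TC":
        total = total + w.lambda_tc_or_st * parts["ltc"]
    elif variant == "ST":
        total = total + w.lambda_tc_or_st * parts["lst"]
    elif variant == "PL":
        total = total + w.lambda_pl * parts["lpl"]
    else:
        total = total + w.lambda_pl * parts["lpl"] \
            + w.lambda_st_cascade * parts["lst"]
    return total
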