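"""Random spatial + intensity augmentation with re-applicable transforms.

A sampled :class:`TransformSpec` freezes every random parameter of one
augmentation draw so the identical warp can be applied to an image, to a
label map (spatial part only, nearest neighbor) and to a soft probability
map (spatial part only, linear, renormalized).  This re-applicability is
what lets transformation-consistency losses align predictions: the target
branch warps predictions with exactly the transform the input saw.

The spatial part composes, about the grid center, scaling, rotation and
translation, followed by an elastic deformation interpolated from a coarse
node grid with cubic B-splines.  Intensity augmentation is a global
affine map; intensities below the MR floor of -1 are clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_preprocess import INTENSITY_FLOOR, ImageSample, LabelMap

__all__ = ["AugmentConfig", "TransformSpec", "sample_transform",
           "apply_to_image", "apply_to_map"]


@dataclass
class AugmentConfig:
    """Uniform sampling ranges for one augmentation draw.

    Pixel-valued ranges (translation, scale_px, elastic_max) refer to a
    grid of ``reference_extent`` pixels per axis; :meth:`for_extent`
    rescales them proportionally for smaller desk-scale grids.  The
    scaling range is expressed as a per-axis size change in pixels and is
    converted to a multiplicative factor ``1 + s/reference_extent``.
    Intensity scaling ``s`` acts as the multiplier ``1 + s``.
    """

    translation: tuple = (-20.0, 20.0)       # pixels
    rotation: tuple = (-0.35, 0.35)          # radians
    scale_px: tuple = (-20.0, 20.0)          # pixels of size change per axis
    reference_extent: int = 160
    elastic: bool = True
    elastic_nodes: int = 8                   # nodes per axis
    elastic_max: float = 15.0                # max displacement, pixels
    intensity_shift: tuple = (-0.2, 0.2)
    intensity_scale: tuple = (-0.4, 0.4)

    def for_extent(self, extent: int) -> "AugmentConfig":
        f = extent / self.reference_extent
        return replace(
            self,
            translation=(self.translation[0] * f, self.translation[1] * f),
            scale_px=(self.scale_px[0] * f, self.scale_px[1] * f),
            elastic_max=self.elastic_max * f,
            reference_extent=extent)

    def without_elastic(self) -> "AugmentConfig":
        return replace(self, elastic=False)

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(translation=(0, 0), rotation=(0, 0), scale_px=(0, 0),
                   elastic=False, intensity_shift=(0, 0), intensity_scale=(0, 0))


@dataclass
class TransformSpec:
    """Frozen parameters of one random spatial + intensity transformation."""

    dim: int
    translation: np.ndarray                  # (dim,) pixels
    rotation: np.ndarray                     # (1,) for 2D, (3,) for 3D
    scale: np.ndarray                        # (dim,) multiplicative factors
    elastic_nodes: Optional[np.ndarray]      # (dim, nodes, ...) or None
    intensity_shift: float = 0.0
    intensity_scale: float = 1.0             # multiplier

    def is_spatial_identity(self) -> bool:
        return (not self.translation.any()
                and not self.rotation.any()
                and np.all(self.scale == 1.0)
                and (self.elastic_nodes is None or not self.elastic_nodes.any()))


def sample_transform(rng: np.random.Generator, cfg: AugmentConfig,
                     dim: int = 2) -> TransformSpec:
    """Draw every parameter uniformly and independently per dimension."""
    translation = rng.uniform(*cfg.translation, size=dim)
    n_rot = 1 if dim == 2 else 3
    rotation = rng.uniform(*cfg.rotation, size=n_rot)
    scale = 1.0 + rng.uniform(*cfg.scale_px, size=dim) / cfg.reference_extent
    nodes = None
    if cfg.elastic:
        nodes = rng.uniform(-cfg.elastic_max, cfg.elastic_max,
                            size=(dim,) + (cfg.elastic_nodes,) * dim)
    shift = rng.uniform(*cfg.intensity_shift)
    scale_i = 1.0 + rng.uniform(*cfg.intensity_scale)
    return TransformSpec(dim, translation, rotation, scale, nodes,
                         float(shift), float(scale_i))


# ---------------------------------------------------------------------------
# applying the spatial part
# ---------------------------------------------------------------------------

def _rotation_matrix(angles: np.ndarray, dim: int) -> np.ndarray:
    if dim == 2:
        c, s = np.cos(angles[0]), np.sin(angles[0])
        return np.array([[c, -s], [s, c]])
    rx, ry, rz = angles
    cx, sx, cy, sy, cz, sz = (np.cos(rx), np.sin(rx), np.cos(ry),
                              np.sin(ry), np.cos(rz), np.sin(rz))
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


def _dense_elastic(nodes: np.ndarray, shape: tuple) -> np.ndarray:
    """Interpolate the coarse node displacements to the full grid (cubic)."""
    dim = nodes.shape[0]
    n_nodes = nodes.shape[1]
    coords = np.meshgrid(
        *[np.linspace(0.0, n_nodes - 1.0, s) for s in shape], indexing="ij")
    return np.stack([
        ndimage.map_coordinates(nodes[d], coords, order=3, mode="nearest")
        for d in range(dim)])


def _sampling_coordinates(spec: TransformSpec, shape: tuple) -> np.ndarray:
    """Source coordinates p(v) such that output[v] = input[p(v)].

    The applied transform is elastic ∘ (translate ∘ rotate ∘ scale about
    the grid center); a pure integer translation t moves content by
    exactly +t pixels.
    """
    if len(shape) != spec.dim:
        raise ValueError(f"spec is {spec.dim}D but data is {len(shape)}D")
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64)
                                  for s in shape], indexing="ij"))
    v = grid
    if spec.elastic_nodes is not None and spec.elastic_nodes.any():
        v = v + _dense_elastic(spec.elastic_nodes, shape)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    a_inv = np.linalg.inv(_rotation_matrix(spec.rotation, spec.dim)
                          @ np.diag(spec.scale))
    offset = v - (center + spec.translation).reshape((-1,) + (1,) * spec.dim)
    p = np.einsum("ij,j...->i...", a_inv, offset)
    return p + center.reshape((-1,) + (1,) * spec.dim)


def apply_to_image(spec: TransformSpec, img: ImageSample) -> ImageSample:
    """Spatial warp (linear, fill -1) then intensity scale/shift, clamped."""
    if img.pixels.ndim != spec.dim:
        raise ValueError("transform and image dimensionality differ")
    if spec.is_spatial_identity():
        out = img.pixels.astype(np.float32, copy=True)
    else:
        coords = _sampling_coordinates(spec, img.pixels.shape)
        out = ndimage.map_coordinates(img.pixels.astype(np.float32), coords,
                                      order=1, mode="constant",
                                      cval=INTENSITY_FLOOR)
    out = out * spec.intensity_scale + spec.intensity_shift
    np.maximum(out, INTENSITY_FLOOR, out=out)
    return img.with_pixels(out.astype(np.float32))


def apply_to_map(spec: TransformSpec, m):
    """Apply only the spatial part of ``spec`` to a label or probability map.

    Label maps warp nearest-neighbor and fill with background.  Probability
    maps (arrays of shape (C, *grid)) warp each channel linearly, fill with
    background probability 1, and are renormalized to sum to one.
    """
    if isinstance(m, LabelMap):
        if m.classes.ndim != spec.dim:
            raise ValueError("transform and label dimensionality differ")
        if spec.is_spatial_identity():
            return LabelMap(m.classes.copy(), m.num_classes)
        coords = _sampling_coordinates(spec, m.classes.shape)
        out = ndimage.map_coordinates(m.classes, coords, order=0,
                                      mode="constant", cval=0)
        return LabelMap(out.astype(m.classes.dtype), m.num_classes)
    probs = np.asarray(m)
    if probs.ndim - 1 != spec.dim:
        raise ValueError("transform and probability-map dimensionality differ")
    if spec.is_spatial_identity():
        return probs.copy()
    coords = _sampling_coordinates(spec, probs.shape[1:])
    out = np.empty_like(probs, dtype=np.float32)
    for c in range(probs.shape[0]):
        out[c] = ndimage.map_coordinates(
            probs[c].astype(np.float32), coords, order=1, mode="constant",
            cval=1.0 if c == 0 else 0.0)
    np.clip(out, 0.0, None, out=out)
    out /= out.sum(axis=0, keepdims=True)
    return out
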