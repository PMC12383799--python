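"""Image/label I/O and preprocessing for cardiac MR segmentation.

Covers reading and writing NIfTI / MetaImage volumes (via SimpleITK),
robust percentile intensity normalization to [-1, 1], Gaussian smoothing,
center-aligned resampling to a fixed grid, and materialization of a 2D
slice dataset from 4D cine stacks with the coverage-based slice exclusion
rule used for the ACDC short-axis data.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

logger = logging.getLogger("cardioseg")

__all__ = [
    "ImageSample",
    "LabelMap",
    "DatasetSplit",
    "SliceDataset",
    "DegenerateInputError",
    "read_volume",
    "write_volume",
    "robust_normalize",
    "gaussian_smooth",
    "smooth_label",
    "resample",
    "prepare_acdc_slices",
]

INTENSITY_FLOOR = -1.0  # MR intensities are clamped here after normalization


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful result (e.g. constant image)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageSample:
    """A 2D or 3D scalar image with physical spacing and sample identity.

    ``pixels`` uses array (z, y, x) axis order; ``spacing`` is mm per axis
    in the same order.
    """

    pixels: np.ndarray
    spacing: tuple
    patient_id: str = ""
    time_index: Optional[int] = None
    sample_id: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.pixels.ndim:
            raise ValueError("spacing must have one entry per image axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on every axis")
        if self.sample_id is None:
            tag = "" if self.time_index is None else f"_t{self.time_index:03d}"
            self.sample_id = f"{self.patient_id}{tag}" if self.patient_id else None

    @property
    def shape(self):
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, spacing=None) -> "ImageSample":
        return ImageSample(pixels, spacing or self.spacing, self.patient_id,
                           self.time_index, self.sample_id, dict(self.metadata))


@dataclass
class LabelMap:
    """Integer class map aligned voxel-for-voxel with an image; 0 = background."""

    classes: np.ndarray
    num_classes: int

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise TypeError("label map must have an integer dtype")
        if self.classes.size and (self.classes.min() < 0
                                  or self.classes.max() >= self.num_classes):
            raise ValueError("label values must lie in [0, num_classes - 1]")

    @property
    def shape(self):
        return self.classes.shape

    def one_hot(self, dtype=np.float32) -> np.ndarray:
        """(num_classes, *shape) one-hot encoding."""
        eye = np.eye(self.num_classes, dtype=dtype)
        return np.moveaxis(eye[self.classes], -1, 0)


@dataclass
class DatasetSplit:
    """Labeled pairs, unlabeled pool and fold identity for one training split.

    In the semi-supervised setup every labeled sample's image also appears
    in the unlabeled pool (Xl is a subset of Xu).  ``labeled_origin`` marks
    each labeled entry as ground truth (``"gt"``) or pseudo-label (``"pl"``)
    so that stage-2 self-training can balance its draws.
    """

    labeled: list            # list[(ImageSample, LabelMap)]
    unlabeled: list          # list[ImageSample]
    fold_id: int = 0
    labeled_origin: Optional[list] = None

    def __post_init__(self):
        if self.labeled_origin is not None and \
                len(self.labeled_origin) != len(self.labeled):
            raise ValueError("labeled_origin must parallel the labeled pool")

    @property
    def gt_indices(self):
        if self.labeled_origin is None:
            return list(range(len(self.labeled)))
        return [i for i, o in enumerate(self.labeled_origin) if o == "gt"]

    @property
    def pl_indices(self):
        if self.labeled_origin is None:
            return []
        return [i for i, o in enumerate(self.labeled_origin) if o == "pl"]

    def check_subset_property(self) -> bool:
        """Xl ⊆ Xu on sample identity."""
        pool = {img.sample_id for img in self.unlabeled}
        return all(img.sample_id in pool for img, _ in self.labeled)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _from_sitk(image: sitk.Image):
    arr = sitk.GetArrayFromImage(image)          # (z, y, x [,components])
    spacing = tuple(reversed(image.GetSpacing()))
    return arr, spacing


def read_volume(path, label: bool = False, patient_id: str = ""):
    """Read a NIfTI or MetaImage file.

    Scalar 2D/3D files yield one :class:`ImageSample` (or :class:`LabelMap`
    with ``label=True``).  4D files (cine time series) yield a list of 3D
    :class:`ImageSample` indexed by time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        image = sitk.ReadImage(str(path))
    except RuntimeError as exc:              # pragma: no cover - sitk detail
        raise IOError(f"unreadable image file: {path}") from exc
    arr, spacing = _from_sitk(image)
    if label:
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"label file {path} has non-integer pixel type {arr.dtype}")
        return LabelMap(arr.astype(np.int32), int(arr.max()) + 1)
    if arr.ndim == 4:                        # (t, z, y, x)
        return [ImageSample(arr[t].astype(np.float32), spacing[1:],
                            patient_id=patient_id or path.stem, time_index=t)
                for t in range(arr.shape[0])]
    return ImageSample(arr.astype(np.float32), spacing,
                       patient_id=patient_id or path.stem)


def write_volume(obj, path) -> None:
    """Write an :class:`ImageSample` or :class:`LabelMap` to NIfTI/MetaImage."""
    if isinstance(obj, LabelMap):
        arr, spacing = obj.classes.astype(np.int16), (1.0,) * obj.classes.ndim
    else:
        arr, spacing = obj.pixels.astype(np.float32), obj.spacing
    image = sitk.GetImageFromArray(arr)
    image.SetSpacing(tuple(reversed(spacing)))
    sitk.WriteImage(image, str(path))


# ---------------------------------------------------------------------------
# intensity preprocessing
# ---------------------------------------------------------------------------

def robust_normalize(img: ImageSample, low_pct: float = 5.0,
                     high_pct: float = 95.0) -> ImageSample:
    """Map the ``low_pct``/``high_pct`` intensity percentiles to -1/+1.

    The map is affine between the two anchor points; values that fall
    below -1 afterwards are clamped to the intensity floor (the same clamp
    used after intensity augmentation).
    """
    if not low_pct < high_pct:
        raise ValueError("low_pct must be smaller than high_pct")
    lo, hi = np.percentile(img.pixels, [low_pct, high_pct])
    if hi <= lo:
        raise DegenerateInputError(
            "intensity percentiles coincide (constant image?)")
    out = 2.0 * (img.pixels.astype(np.float32) - lo) / (hi - lo) - 1.0
    np.maximum(out, INTENSITY_FLOOR, out=out)
    return img.with_pixels(out)


def gaussian_smooth(img: ImageSample, sigma: float) -> ImageSample:
    """Isotropic Gaussian smoothing in grid units; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return img.with_pixels(img.pixels.copy())
    return img.with_pixels(
        ndimage.gaussian_filter(img.pixels.astype(np.float32), sigma,
                                mode="nearest"))


def smooth_label(label: LabelMap, sigma: float) -> LabelMap:
    """Smooth one-hot channels then re-argmax (class maps cannot be averaged)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return LabelMap(label.classes.copy(), label.num_classes)
    probs = label.one_hot()
    for c in range(label.num_classes):
        probs[c] = ndimage.gaussian_filter(probs[c], sigma, mode="nearest")
    return LabelMap(np.argmax(probs, axis=0).astype(label.classes.dtype),
                    label.num_classes)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _resample_array(arr: np.ndarray, src_spacing: Sequence[float],
                    target_shape: Sequence[int],
                    target_spacing: Sequence[float], order: int) -> np.ndarray:
    """Center-aligned resampling: physical centers of both grids coincide."""
    coords = np.meshgrid(
        *[(np.arange(n_t) - (n_t - 1) / 2.0) * (sp_t / sp_s) + (n_s - 1) / 2.0
          for n_t, sp_t, n_s, sp_s in zip(target_shape, target_spacing,
                                          arr.shape, src_spacing)],
        indexing="ij")
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def resample(obj, target_shape, target_spacing, mode: Optional[str] = None,
             src_spacing=None):
    """Resample to ``target_shape`` voxels at ``target_spacing`` mm.

    Images use linear interpolation, label maps nearest neighbor.  The
    physical field of view is aligned on the grid centers.  Label maps do
    not carry spacing themselves: pass ``src_spacing`` (the spacing of the
    paired image); if omitted it is derived so that the physical field of
    view is preserved.
    """
    target_shape = tuple(int(n) for n in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(n <= 0 for n in target_shape) or any(s <= 0 for s in target_spacing):
        raise ValueError("target shape and spacing must be positive")
    if mode is None:
        mode = "label" if isinstance(obj, LabelMap) else "image"
    if mode == "label":
        if not isinstance(obj, LabelMap):
            raise TypeError("mode='label' requires a LabelMap (integer grid)")
        if src_spacing is None:
            src_spacing = tuple(sp_t * n_t / n_s for sp_t, n_t, n_s in
                                zip(target_spacing, target_shape, obj.shape))
        out = _resample_array(obj.classes, src_spacing, target_shape,
                              target_spacing, order=0)
        return LabelMap(out.astype(obj.classes.dtype), obj.num_classes)
    if not isinstance(obj, ImageSample):
        raise TypeError("mode='image' requires an ImageSample")
    out = _resample_array(obj.pixels.astype(np.float32),
                          src_spacing or obj.spacing,
                          target_shape, target_spacing, order=1)
    return ImageSample(out, target_spacing, obj.patient_id, obj.time_index,
                       obj.sample_id, dict(obj.metadata))


# ---------------------------------------------------------------------------
# ACDC-style slice dataset
# ---------------------------------------------------------------------------

@dataclass
class SliceDataset:
    """Output of :func:`prepare_acdc_slices`."""

    labeled: list                 # list[(ImageSample, LabelMap)] — annotated time steps
    unlabeled: list               # list[ImageSample] — all time steps, retained slices
    n_retained: int
    n_excluded: int
    skipped_patients: list


def prepare_acdc_slices(volumes4d: dict, labels: dict,
                        min_label_fraction: float = 0.0007) -> SliceDataset:
    """Materialize the 2D slice dataset from 4D cine stacks.

    ``volumes4d`` maps patient id -> time-ordered list of 3D ImageSamples;
    ``labels`` maps patient id -> {time_index: LabelMap} with exactly the
    two annotated time steps (end diastole / end systole).

    A slice *position* z is excluded when, in either annotated time step,
    any foreground class covers strictly less than ``min_label_fraction``
    of the slice area.  Labeled output slices come only from the two
    annotated time steps; the unlabeled pool holds the retained slice
    positions from every time step (so Xl ⊆ Xu).

    Patients whose out-of-plane orientation (metadata key
    ``"out_of_plane"``) differs from the majority are skipped with a log
    entry rather than silently included.
    """
    if not 0 < min_label_fraction < 1:
        raise ValueError("min_label_fraction must lie in (0, 1)")
    orientations = [vols[0].metadata.get("out_of_plane")
                    for vols in volumes4d.values() if vols]
    known = [o for o in orientations if o is not None]
    majority = max(set(known), key=known.count) if known else None

    labeled_out, unlabeled_out, skipped = [], [], []
    n_retained = n_excluded = 0
    for pid, vols in volumes4d.items():
        if pid not in labels or len(labels[pid]) < 2:
            raise ValueError(f"patient {pid} needs >= 2 labeled time steps")
        orient = vols[0].metadata.get("out_of_plane")
        if majority is not None and orient is not None and orient != majority:
            logger.warning("skipping patient %s: out-of-plane orientation %r "
                           "differs from majority %r", pid, orient, majority)
            skipped.append(pid)
            continue
        lab_times = sorted(labels[pid])
        num_classes = max(labels[pid][t].num_classes for t in lab_times)
        nz = vols[0].pixels.shape[0]
        area = float(np.prod(vols[0].pixels.shape[1:]))
        for z in range(nz):
            keep = True
            for t in lab_times:
                sl = labels[pid][t].classes[z]
                for c in range(1, num_classes):
                    if np.count_nonzero(sl == c) / area < min_label_fraction:
                        keep = False
                        break
                if not keep:
                    break
            if not keep:
                n_excluded += len(vols)
                continue
            n_retained += len(vols)
            for t, vol in enumerate(vols):
                img2d = ImageSample(vol.pixels[z], vol.spacing[1:],
                                    patient_id=pid, time_index=t,
                                    sample_id=f"{pid}_t{t:03d}_z{z:03d}")
                unlabeled_out.append(img2d)
                if t in lab_times:
                    lab2d = LabelMap(labels[pid][t].classes[z], num_classes)
                    labeled_out.append((img2d, lab2d))
    return SliceDataset(labeled_out, unlabeled_out, n_retained, n_excluded,
                        skipped)
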