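"""Evaluation metrics: multi-class DSC, ASSD, and cross-validation aggregation.

DSC per foreground class c is 2|y_c ∩ ŷ_c| / (|y_c| + |ŷ_c|), reported in
percent and averaged (unweighted) over the class set.  ASSD is the
symmetric mean of nearest-boundary Euclidean distances in physical mm: a
voxel is a boundary voxel when it belongs to the class and has a
face-adjacent neighbor (or the image border) outside the class; distances
run between boundary-voxel centers in physical coordinates.

Conventions for degenerate classes: a class empty in both masks scores
DSC 100% / ASSD 0 mm (perfect agreement on absence); a class empty in
exactly one mask has undefined ASSD and is reported as NaN with a warning.

Predictions made on the network grid are evaluated against the untouched
original-ground-truth grid by linearly resampling the probability channels
to the original spacing before the argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preprocess import LabelMap, _resample_array

__all__ = ["MetricReport", "dice_multiclass", "assd",
           "evaluate_prediction", "aggregate_cv", "boundary_mask"]


@dataclass
class MetricReport:
    """Per-class and mean DSC (percent) / ASSD (mm) for one sample."""

    per_class_dsc: Dict[int, float]
    mean_dsc: float
    per_class_assd: Dict[int, float]
    mean_assd: float
    sample_id: Optional[str] = None
    fold: int = 0
    repetition: int = 0

    def as_record(self) -> dict:
        rec = {"sample_id": self.sample_id, "fold": self.fold,
               "repetition": self.repetition, "mean_dsc": self.mean_dsc,
               "mean_assd": self.mean_assd}
        rec.update({f"dsc_{c}": v for c, v in self.per_class_dsc.items()})
        rec.update({f"assd_{c}": v for c, v in self.per_class_assd.items()})
        return rec


def _foreground_classes(gt: LabelMap, classes) -> list:
    if classes is None:
        return list(range(1, gt.num_classes))
    return sorted(int(c) for c in classes)


def dice_multiclass(gt: LabelMap, pred: LabelMap,
                    classes: Optional[Iterable[int]] = None):
    """Per-class and mean DSC in percent; empty-empty classes score 100."""
    if gt.shape != pred.shape:
        raise ValueError("ground truth and prediction grids differ")
    out = {}
    for c in _foreground_classes(gt, classes):
        a = gt.classes == c
        b = pred.classes == c
        na, nb = int(a.sum()), int(b.sum())
        if na + nb == 0:
            out[c] = 100.0
        else:
            out[c] = 200.0 * int((a & b).sum()) / (na + nb)
    return out, float(np.mean(list(out.values())))


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with a face-adjacent neighbor outside the class.

    The image border counts as outside, so mask voxels on the edge of the
    grid are boundary voxels.
    """
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def assd(gt: LabelMap, pred: LabelMap,
         classes: Optional[Iterable[int]] = None,
         spacing: Sequence[float] = None):
    """Per-class and mean ASSD in mm.

    A class empty in exactly one of the two masks yields NaN for that
    class (undefined surface distance) with a warning; the mean skips NaN
    entries.
    """
    if gt.shape != pred.shape:
        raise ValueError("ground truth and prediction grids differ")
    if spacing is None:
        spacing = (1.0,) * gt.classes.ndim
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    out = {}
    for c in _foreground_classes(gt, classes):
        a = gt.classes == c
        b = pred.classes == c
        if not a.any() and not b.any():
            out[c] = 0.0
            continue
        if a.any() != b.any():
            warnings.warn(f"class {c} empty in exactly one mask: ASSD undefined")
            out[c] = float("nan")
            continue
        ba, bb = boundary_mask(a), boundary_mask(b)
        dist_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
        dist_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
        total = dist_to_b[ba].sum() + dist_to_a[bb].sum()
        out[c] = float(total / (ba.sum() + bb.sum()))
    vals = [v for v in out.values() if not np.isnan(v)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return out, mean


def evaluate_prediction(pred_prob: np.ndarray, original_gt: LabelMap,
                        original_spacing: Sequence[float],
                        pred_spacing: Optional[Sequence[float]] = None,
                        classes: Optional[Iterable[int]] = None,
                        sample_id: Optional[str] = None,
                        fold: int = 0, repetition: int = 0) -> MetricReport:
    """Resample probabilities to the original grid, argmax, then score.

    ``pred_prob`` has shape (C, *network_grid).  If ``pred_spacing`` is not
    given it is derived assuming the network grid covers the same physical
    field of view as the ground-truth grid.  The ground truth itself is
    never modified.
    """
    pred_prob = np.asarray(pred_prob)
    original_spacing = tuple(float(s) for s in original_spacing)
    tgt_shape = original_gt.shape
    if pred_spacing is None:
        pred_spacing = tuple(sp * nt / ns for sp, nt, ns in
                             zip(original_spacing, tgt_shape, pred_prob.shape[1:]))
    if pred_prob.shape[1:] == tuple(tgt_shape) \
            and tuple(pred_spacing) == original_spacing:
        resampled = pred_prob
    else:
        resampled = np.stack([
            _resample_array(pred_prob[c], pred_spacing, tgt_shape,
                            original_spacing, order=1)
            for c in range(pred_prob.shape[0])])
    pred_labels = LabelMap(np.argmax(resampled, axis=0).astype(np.int32),
                           original_gt.num_classes)
    per_dsc, mean_dsc = dice_multiclass(original_gt, pred_labels, classes)
    per_assd, mean_assd = assd(original_gt, pred_labels, classes,
                               original_spacing)
    return MetricReport(per_dsc, mean_dsc, per_assd, mean_assd,
                        sample_id=sample_id, fold=fold, repetition=repetition)


def aggregate_cv(reports, value_columns=("mean_dsc", "mean_assd")) -> pd.DataFrame:
    """μ ± σ over cross-validation folds with repeated runs.

    ``reports`` is an iterable of :class:`MetricReport` (or records with
    ``fold``/``repetition``/``sample_id`` keys).  Per (fold, sample) the
    values are first averaged over repetitions, and the spread over
    repetitions is recorded; μ is the grand mean of the per-sample
    averages, σ their sample standard deviation pooled across folds, and
    ``mean_repetition_sigma`` the average per-sample repetition spread.
    A single repetition yields zero repetition spread (with a warning).
    """
    records = [r.as_record() if isinstance(r, MetricReport) else dict(r)
               for r in reports]
    if not records:
        raise ValueError("no reports to aggregate")
    df = pd.DataFrame.from_records(records)
    if df["repetition"].nunique() < 2:
        warnings.warn("single repetition: σ over repetitions is 0")
    rows = []
    grouped = df.groupby(["fold", "sample_id"], sort=True)
    for col in value_columns:
        per_sample_mean = grouped[col].mean()
        per_sample_sigma = grouped[col].std(ddof=0).fillna(0.0)
        mu = float(per_sample_mean.mean())
        sigma = float(per_sample_mean.std(ddof=1)) \
            if len(per_sample_mean) > 1 else 0.0
        rows.append({"metric": col, "mu": mu, "sigma": sigma,
                     "mean_repetition_sigma": float(per_sample_sigma.mean()),
                     "n_samples": int(len(per_sample_mean))})
    return pd.DataFrame(rows).set_index("metric")
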