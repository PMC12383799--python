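"""Synthetic multi-compartment cardiac-like phantoms with patient structure.

Every trainer, cascade and metric in this package is testable end-to-end
without external data through this generator.  Two label topologies are
emulated:

* ``num_classes=4`` (short-axis cine style): a left-ventricle blood-pool
  disc (class 3) fully enclosed by a myocardium annulus (class 2), with an
  adjacent right-ventricle crescent (class 1) — the nested/adjacent
  topology of short-axis cardiac MR slices.
* ``num_classes=8`` (whole-heart style): seven adjacent elliptical blobs
  arranged around the grid center.

Shapes are analytic (discs, annuli, crescents, ellipses) so containment
and area oracles are exact.  Every *patient* draws one set of anatomical
and contrast latents (radii, ellipse aspect/orientation, per-class
intensity means); the patient's samples are small jitters of those
latents, like time points of a cine acquisition.  Labeling is granted per
patient, mirroring clinical annotation practice: a low labeled fraction
therefore means few labeled *anatomies*, which a supervised model
undersamples while the unlabeled pool still spans the population — the
regime in which semi-supervision has something to add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .io_preprocess import DatasetSplit, ImageSample, LabelMap, \
    gaussian_smooth, robust_normalize

__all__ = ["PhantomConfig", "generate_phantom", "generate_split"]


@dataclass
class PhantomConfig:
    """Geometry, intensity and noise settings for phantom generation.

    Radii and offsets are fractions of the grid extent, so the same config
    scales from desk-size 48² grids to 160² without re-tuning.
    """

    dim: int = 2
    grid: Tuple[int, ...] = (64, 64)
    num_classes: int = 4                 # 4 = bg + 3 (cine-like), 8 = bg + 7
    spacing: Optional[Tuple[float, ...]] = None
    # position variation comes mostly from the training-time augmentation
    # (as after center-cropping in a real pipeline); jitter is residual
    center_jitter: float = 0.02          # fraction of extent
    lv_radius: Tuple[float, float] = (0.08, 0.14)
    myo_thickness: Tuple[float, float] = (0.06, 0.09)
    rv_radius: Tuple[float, float] = (0.12, 0.16)
    rv_angle_jitter: float = 0.3         # radians around the anatomical side
    # the LV/MYO cross-section is an ellipse with per-patient aspect ratio
    # and orientation: inter-patient shape variation a small labeled set
    # cannot fully cover
    lv_aspect: Tuple[float, float] = (0.80, 0.95)
    lv_orientation: Tuple[float, float] = (-0.6, 0.6)   # radians
    blob_radius: Tuple[float, float] = (0.08, 0.13)   # 8-class mode
    intensity_means: Optional[Tuple[float, ...]] = None
    # per-patient spread of the class means: scanner/sequence-like contrast
    # variation that global intensity augmentation cannot imitate
    intensity_jitter: float = 0.10
    noise_sd: float = 0.10
    smooth_sigma: float = 1.0            # preprocessing smoothing, grid units
    # how far a patient's samples wander around the patient latents,
    # as a fraction of the corresponding population range
    intra_patient_jitter: float = 0.25

    def __post_init__(self):
        self.grid = tuple(int(g) for g in self.grid)
        if len(self.grid) != self.dim:
            raise ValueError("grid must have one extent per dimension")
        if any(g % 16 for g in self.grid):
            raise ValueError("grid extents must be divisible by 16")
        if self.num_classes not in (4, 8):
            raise ValueError("num_classes must be 4 or 8")
        if self.spacing is None:
            self.spacing = (1.0,) * self.dim
        if self.intensity_means is None:
            if self.num_classes == 4:
                # bg, RV blood, myocardium, LV blood
                self.intensity_means = (0.15, 0.45, 0.30, 0.60)
            else:
                self.intensity_means = tuple(
                    0.15 + 0.07 * k for k in range(8))
        if len(self.intensity_means) != self.num_classes:
            raise ValueError("need one intensity mean per class")
        # feasibility: the largest shape constellation must fit the grid.
        # The RV far rim reaches (r_lv + thickness)/sqrt(aspect) + 1.55 r_rv
        # from the (jittered) grid center; a slight (1-2 px) clipping at
        # extreme draws is tolerated, as after center-cropping real
        # acquisitions — error out only when shapes grossly exceed the grid
        extent = min(self.grid)
        stretch = 1.0 / math.sqrt(self.lv_aspect[0])
        reach = ((self.lv_radius[1] + self.myo_thickness[1]) * stretch
                 + 1.55 * self.rv_radius[1] + self.center_jitter)
        if self.num_classes == 4 and reach >= 0.55:
            raise ValueError(
                f"shape jitter infeasible: max radial reach {reach:.2f} of "
                f"the extent exceeds the grid half-width")
        if extent * self.lv_radius[0] < 1.5:
            raise ValueError("grid too small for the configured LV radius")


# ---------------------------------------------------------------------------
# latent sampling (per patient) and jittering (per sample within a patient)
# ---------------------------------------------------------------------------

def _sample_latents(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    lat = {
        "center_frac": rng.uniform(-cfg.center_jitter, cfg.center_jitter,
                                   cfg.dim),
        "means": np.asarray(cfg.intensity_means, dtype=np.float64)
        + (rng.uniform(-cfg.intensity_jitter, cfg.intensity_jitter,
                       cfg.num_classes) if cfg.intensity_jitter > 0 else 0.0),
    }
    if cfg.num_classes == 4:
        lat.update(
            r_lv=rng.uniform(*cfg.lv_radius),
            myo_th=rng.uniform(*cfg.myo_thickness),
            r_rv=rng.uniform(*cfg.rv_radius),
            theta=rng.uniform(-cfg.rv_angle_jitter, cfg.rv_angle_jitter),
            phi=rng.uniform(-cfg.rv_angle_jitter, cfg.rv_angle_jitter),
            aspect=rng.uniform(*cfg.lv_aspect),
            orientation=rng.uniform(*cfg.lv_orientation))
    else:
        lat.update(
            blob_angles=[2.0 * math.pi * k / 7.0 + rng.uniform(-0.15, 0.15)
                         for k in range(7)],
            blob_z=[rng.uniform(-0.1, 0.1) for _ in range(7)],
            blob_semi=[rng.uniform(*cfg.blob_radius, size=cfg.dim)
                       for _ in range(7)])
    return lat


def _jitter_latents(lat: dict, cfg: PhantomConfig,
                    rng: np.random.Generator) -> dict:
    """Intra-patient variation: wander around the patient latents by a
    fraction of each population range (like cine time points)."""
    f = cfg.intra_patient_jitter

    def j(value, lo, hi):
        return np.clip(value + rng.uniform(-f, f) * (hi - lo), lo, hi)

    out = dict(lat)
    out["center_frac"] = lat["center_frac"] + rng.uniform(
        -f * cfg.center_jitter, f * cfg.center_jitter, cfg.dim)
    out["means"] = lat["means"] + rng.uniform(
        -f * cfg.intensity_jitter, f * cfg.intensity_jitter, cfg.num_classes)
    if cfg.num_classes == 4:
        out["r_lv"] = j(lat["r_lv"], *cfg.lv_radius)
        out["myo_th"] = j(lat["myo_th"], *cfg.myo_thickness)
        out["r_rv"] = j(lat["r_rv"], *cfg.rv_radius)
        out["theta"] = j(lat["theta"], -cfg.rv_angle_jitter,
                         cfg.rv_angle_jitter)
        out["aspect"] = j(lat["aspect"], *cfg.lv_aspect)
        out["orientation"] = j(lat["orientation"], *cfg.lv_orientation)
    return out


def _distance_grid(shape, center):
    axes = [np.arange(s, dtype=np.float64) for s in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum((m - c) ** 2 for m, c in zip(mesh, center)))


def _elliptic_distance(shape, center, aspect: float, orientation: float):
    """Distance in a frame where the LV ellipse becomes a circle.

    Semi-axes r/sqrt(aspect) and r*sqrt(aspect) preserve the enclosed
    area of a circle with radius r.  In 3D the elongation is applied in
    the in-plane (y, x) axes only.
    """
    axes = [np.arange(s, dtype=np.float64) for s in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    dy = mesh[-2] - center[-2]
    dx = mesh[-1] - center[-1]
    c, s = math.cos(orientation), math.sin(orientation)
    u = (c * dy + s * dx) * math.sqrt(aspect)
    v = (-s * dy + c * dx) / math.sqrt(aspect)
    d2 = u ** 2 + v ** 2
    if len(shape) == 3:
        d2 = d2 + (mesh[0] - center[0]) ** 2
    return np.sqrt(d2)


def _cine_labels(cfg: PhantomConfig, lat: dict) -> np.ndarray:
    extent = float(min(cfg.grid))
    center = np.array(cfg.grid, dtype=np.float64) / 2.0 \
        + lat["center_frac"] * extent
    r_lv = lat["r_lv"] * extent
    r_myo = r_lv + lat["myo_th"] * extent
    r_rv = lat["r_rv"] * extent
    aspect, orientation = lat["aspect"], lat["orientation"]
    # the RV sits on a consistent anatomical side of the LV in short-axis
    # views; emulate that with a fixed base direction plus angular jitter
    theta = -math.pi / 2.0 + lat["theta"]
    if cfg.dim == 2:
        direction = np.array([math.sin(theta), math.cos(theta)])
    else:
        phi = math.pi / 2.0 + lat["phi"]
        direction = np.array([math.cos(phi),
                              math.sin(phi) * math.sin(theta),
                              math.sin(phi) * math.cos(theta)])
    # place the RV just outside the (elliptical) epicardial boundary along
    # the sampled direction
    dy, dx = direction[-2], direction[-1]
    c0, s0 = math.cos(orientation), math.sin(orientation)
    m = math.sqrt(aspect * (c0 * dy + s0 * dx) ** 2
                  + (-s0 * dy + c0 * dx) ** 2 / aspect)
    c_rv = center + (r_myo / m + 0.55 * r_rv) * direction

    d_lv = _elliptic_distance(cfg.grid, center, aspect, orientation)
    d_rv = _distance_grid(cfg.grid, c_rv)
    labels = np.zeros(cfg.grid, dtype=np.int32)
    labels[(d_rv <= r_rv) & (d_lv > r_myo)] = 1      # RV crescent
    labels[(d_lv <= r_myo) & (d_lv > r_lv)] = 2      # myocardium annulus
    labels[d_lv <= r_lv] = 3                         # LV blood pool
    return labels


def _blob_labels(cfg: PhantomConfig, lat: dict) -> np.ndarray:
    extent = float(min(cfg.grid))
    center = np.array(cfg.grid, dtype=np.float64) / 2.0
    labels = np.zeros(cfg.grid, dtype=np.int32)
    ring = 0.27 * extent
    axes = [np.arange(s, dtype=np.float64) for s in cfg.grid]
    mesh = np.meshgrid(*axes, indexing="ij")
    for k in range(7):                   # earlier classes win overlaps
        angle = lat["blob_angles"][k]
        if cfg.dim == 2:
            offset = ring * np.array([math.sin(angle), math.cos(angle)])
        else:
            offset = np.array([lat["blob_z"][k] * extent,
                               ring * math.sin(angle),
                               ring * math.cos(angle)])
        c_k = center + offset
        semi = lat["blob_semi"][k] * extent
        inside = sum(((m - c) / a) ** 2
                     for m, c, a in zip(mesh, c_k, semi)) <= 1.0
        labels[inside & (labels == 0)] = k + 1
    return labels


def _render(cfg: PhantomConfig, lat: dict, rng: np.random.Generator,
            patient_id: str, time_index: Optional[int]):
    labels = _cine_labels(cfg, lat) if cfg.num_classes == 4 \
        else _blob_labels(cfg, lat)
    pixels = lat["means"][labels]
    if cfg.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, cfg.noise_sd, size=labels.shape)
    img = ImageSample(pixels.astype(np.float32), cfg.spacing,
                      patient_id=patient_id, time_index=time_index)
    if cfg.smooth_sigma > 0:             # the preprocessing pipeline's step
        img = gaussian_smooth(img, cfg.smooth_sigma)
    img = robust_normalize(img)
    return img, LabelMap(labels, cfg.num_classes)


def generate_phantom(cfg: PhantomConfig, rng: np.random.Generator,
                     patient_id: str = "phantom",
                     time_index: Optional[int] = None):
    """One (image, label) pair with fresh latents; deterministic given rng."""
    return _render(cfg, _sample_latents(cfg, rng), rng, patient_id,
                   time_index)


def generate_split(cfg: PhantomConfig, n_total: int, labeled_fraction: float,
                   seed: int, n_test: int = 20, fold_id: int = 0,
                   samples_per_patient: int = 4):
    """A semi-supervised phantom split plus a disjoint labeled test set.

    ``n_total`` samples are generated as ``n_total / samples_per_patient``
    patients, each contributing jittered variations of its anatomy.
    Labeling is granted per patient: ``ceil(fraction * n_patients)``
    randomly chosen patients contribute all their samples to Xl.  Every
    generated sample (labeled ones included) enters the unlabeled pool,
    mirroring the Xl ⊆ Xu convention.  Test samples come from a derived
    seed and from patients disjoint from the training set.
    """
    if n_total < 2:
        raise ValueError("need at least two phantoms")
    if not 0 < labeled_fraction <= 1:
        raise ValueError("labeled_fraction must lie in (0, 1]")
    if samples_per_patient < 1:
        raise ValueError("samples_per_patient must be >= 1")
    train_seed, test_seed = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(train_seed)
    n_patients = max(2, math.ceil(n_total / samples_per_patient))

    by_patient = []
    made = 0
    for p in range(n_patients):
        lat = _sample_latents(cfg, rng)
        pid = f"phantom{p:04d}"
        samples = []
        for t in range(min(samples_per_patient, n_total - made)):
            samples.append(_render(cfg, _jitter_latents(lat, cfg, rng),
                                   rng, pid, t))
            made += 1
        if samples:
            by_patient.append(samples)

    n_labeled_patients = math.ceil(labeled_fraction * len(by_patient))
    labeled_ids = sorted(rng.choice(len(by_patient), size=n_labeled_patients,
                                    replace=False))
    split = DatasetSplit(
        labeled=[pair for p in labeled_ids for pair in by_patient[p]],
        unlabeled=[img for samples in by_patient for img, _ in samples],
        fold_id=fold_id)

    rng_test = np.random.default_rng(test_seed)
    test_pairs = [generate_phantom(cfg, rng_test, patient_id=f"test{k:04d}")
                  for k in range(n_test)]
    return split, test_pairs
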