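"""Single-stage training strategies: SV, TC, STnoTC and STTC.

Each iteration draws one labeled sample (plus one unlabeled sample for the
semi-supervised strategies), augments them, runs the student, composes the
variant's total loss and takes one Adam step.  The consistency paths are
switched on as a hard switch at ``switch_fraction`` of the iteration
budget (the first half of training is purely supervised); for the
student-teacher strategies the teacher is created at the switch as a copy
of the student and from then on follows the exponential moving average
θT ← α θT + (1 − α) θS after every student update.  The teacher is never
touched by the optimizer and its outputs are gradient-detached targets.

Random-number use is split into independent streams (parameter init,
labeled draw, unlabeled draw, labeled/unlabeled augmentation, supervised/
unsupervised dropout) so that disabling the unsupervised path — an empty
unlabeled pool or a zero consistency weight — leaves the supervised
trajectory bit-identical to plain SV training under the same seed.

When the split carries pseudo-labeled entries (stage 2 of a pseudo-label
cascade) each iteration additionally draws one pseudo-labeled sample; its
generalized Dice term LPL is treated as supervised (active from iteration
0) while only the consistency term obeys the half-way switch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from typing import Callable, Dict, Optional

import numpy as np

from . import network
from .augment import AugmentConfig, apply_to_image, apply_to_map, sample_transform
from .io_preprocess import DatasetSplit
from .losses import LossWeights, compose_total_loss, consistency_mse, \
    generalized_dice_loss
from .network import ModelParams

__all__ = ["ScheduleConfig", "TrainState", "AdamState", "STRATEGIES",
           "lr_at_iteration", "ema_update", "sample_training_pair",
           "train_stage"]

STRATEGIES = ("SV", "TC", "STnoTC", "STTC")
_ST_STRATEGIES = ("STnoTC", "STTC")


class ConfigurationError(ValueError):
    """Raised when a split or strategy configuration is unusable."""


@dataclass
class ScheduleConfig:
    """Iteration budget, learning-rate decay, EMA factor and switch point.

    ``warmup_fraction`` linearly ramps the learning rate from 0 over the
    first part of training before the exponential decay applies.  It
    defaults to 0 (plain exponential decay).  Short-budget training needs
    it: with Adam, the volume-weighted Dice loss produces a large,
    sign-consistent early gradient that suppresses small classes faster
    than their features can form, to the point of float32 softmax
    underflow from which no recovery is possible.
    """

    total_iterations: int
    lr0: float = 1e-4
    decay_rate: float = 0.1
    alpha_ema: float = 0.999
    switch_fraction: float = 0.5
    warmup_fraction: float = 0.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if not 0 <= self.alpha_ema <= 1:
            raise ValueError("alpha_ema must lie in [0, 1]")
        if not 0 <= self.switch_fraction <= 1:
            raise ValueError("switch_fraction must lie in [0, 1]")
        if not 0 <= self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must lie in [0, 1)")

    @property
    def switch_iteration(self) -> int:
        return int(round(self.switch_fraction * self.total_iterations))


def lr_at_iteration(i: int, total: int, cfg: ScheduleConfig) -> float:
    """lr(i) = lr0 · decay_rate^(i/total), monotone decreasing, times a
    linear ramp from 0 during the optional warm-up."""
    if total <= 0:
        raise ValueError("total iterations must be positive")
    if not 0 <= i <= total:
        raise ValueError("iteration index out of range")
    lr = cfg.lr0 * cfg.decay_rate ** (i / total)
    n_warm = cfg.warmup_fraction * total
    if i < n_warm:
        lr *= (i + 1) / n_warm
    return lr


def ema_update(teacher: ModelParams, student: ModelParams,
               alpha: float) -> ModelParams:
    """θT ← α·θT + (1 − α)·θS elementwise; the teacher gets no gradients."""
    if set(teacher.params) != set(student.params):
        raise ValueError("teacher and student parameter structures differ")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    return teacher.linear_combination(student, alpha)


def sample_training_pair(split: DatasetSplit, rng: np.random.Generator,
                         need_unlabeled: bool = True):
    """One uniform labeled draw (with label) and one uniform unlabeled draw."""
    if not split.labeled:
        raise ConfigurationError("labeled pool is empty")
    labeled = split.labeled[rng.integers(len(split.labeled))]
    unlabeled = None
    if need_unlabeled:
        if not split.unlabeled:
            raise ConfigurationError("unlabeled pool is empty")
        unlabeled = split.unlabeled[rng.integers(len(split.unlabeled))]
    return labeled, unlabeled


class AdamState:
    """Adam with bias correction; state per named parameter tensor."""

    def __init__(self, params: Dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        c1 = 1.0 - self.beta1 ** self.t
        c2 = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            params[k] -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


@dataclass
class TrainState:
    """Mutable training state handed to ``on_iteration`` callbacks."""

    student: ModelParams
    teacher: Optional[ModelParams]
    iteration: int
    total_iterations: int
    optimizer: AdamState
    rngs: Dict[str, np.random.Generator] = field(default_factory=dict)


def _derive_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] & 0x7FFFFFFF)


def train_stage(strategy: str, split: DatasetSplit, schedule: ScheduleConfig,
                weights: LossWeights, seed: int, *,
                dim: int = 2, num_classes: Optional[int] = None,
                base_channels: int = 64, dropout_rate: float = 0.1,
                augment_cfg: Optional[AugmentConfig] = None,
                on_iteration: Optional[Callable] = None,
                log_path=None, log_every: int = 1) -> ModelParams:
    """Run one full training stage and return the trained student.

    ``augment_cfg`` describes the unlabeled-sample transform TF (elastic
    deformation included); labeled samples are augmented with the same
    ranges but without elastic deformation.  With ``augment_cfg=None`` the
    ranges default to :class:`AugmentConfig` scaled to the image extent.
    """
    strategy = {s.lower(): s for s in STRATEGIES}.get(strategy.lower())
    if strategy is None:
        raise ConfigurationError(f"unknown strategy (use one of {STRATEGIES})")
    if not split.labeled:
        raise ConfigurationError("labeled pool is empty")

    example_img, example_lab = split.labeled[0]
    if num_classes is None:
        num_classes = example_lab.num_classes
    extent = min(example_img.shape)
    if augment_cfg is None:
        augment_cfg = AugmentConfig().for_extent(extent)
    aug_labeled = augment_cfg.without_elastic()

    streams = np.random.SeedSequence(seed).spawn(7)
    init_seed = _derive_seed(streams[0])
    rngs = {
        "labeled_draw": np.random.default_rng(streams[1]),
        "unlabeled_draw": np.random.default_rng(streams[2]),
        "aug_labeled": np.random.default_rng(streams[3]),
        "aug_unlabeled": np.random.default_rng(streams[4]),
        "dropout_sup": np.random.default_rng(streams[5]),
        "dropout_unsup": np.random.default_rng(streams[6]),
    }

    student = network.build_unet(dim, num_classes, init_seed,
                                 base_channels=base_channels,
                                 dropout_rate=dropout_rate)
    teacher: Optional[ModelParams] = None
    optimizer = AdamState(student.params, schedule.adam_beta1,
                          schedule.adam_beta2, schedule.adam_eps)
    state = TrainState(student, teacher, 0, schedule.total_iterations,
                       optimizer, rngs)

    pl_mode = bool(split.pl_indices)
    gt_pool = split.gt_indices
    pl_pool = split.pl_indices
    is_st = strategy in _ST_STRATEGIES
    cons_weight = weights.lambda_st_cascade if (is_st and pl_mode) else \
        weights.lambda_tc_or_st
    unsup_possible = (strategy != "SV" and cons_weight > 0
                      and len(split.unlabeled) > 0)
    switch = schedule.switch_iteration

    log_fh = open(log_path, "w") if log_path else None
    try:
        for i in range(schedule.total_iterations):
            lr = lr_at_iteration(i, schedule.total_iterations, schedule)
            unsup_active = unsup_possible and i >= switch
            if is_st and unsup_possible and i == switch:
                teacher = student.copy()
                state.teacher = teacher

            def supervised_term(pool, aug_rng):
                idx = pool[rngs["labeled_draw"].integers(len(pool))]
                img, lab = split.labeled[idx]
                spec = sample_transform(aug_rng, aug_labeled, dim)
                x = apply_to_image(spec, img).pixels
                y = apply_to_map(spec, lab)
                probs, lv = network.forward(
                    student, x, training=True, rng=rngs["dropout_sup"],
                    requires_grad=True, leaves=leaves)
                return generalized_dice_loss(probs, y), lv, idx

            leaves = None
            lsv, leaves, idx_gt = supervised_term(gt_pool, rngs["aug_labeled"])
            record = {"iteration": i, "lr": lr, "lsv": lsv.item(),
                      "strategy": strategy, "labeled_index": idx_gt,
                      "consistency_weight": cons_weight if unsup_active else 0.0}

            parts = {"lsv": lsv}
            # the pseudo-label term is a supervised loss component (targets
            # are fixed label maps), so it is active from iteration 0; only
            # the consistency paths obey the half-way switch
            if pl_mode:
                lpl, leaves, idx_pl = supervised_term(pl_pool,
                                                      rngs["aug_labeled"])
                parts["lpl"] = lpl
                record["lpl"] = lpl.item()
                record["pl_index"] = idx_pl

            if unsup_active:
                xu = split.unlabeled[
                    rngs["unlabeled_draw"].integers(len(split.unlabeled))]
                record["unlabeled_id"] = xu.sample_id
                if strategy == "TC":
                    spec = sample_transform(rngs["aug_unlabeled"],
                                            augment_cfg, dim)
                    target = apply_to_map(spec, network.predict(
                        student, xu, training=True,
                        rng=rngs["dropout_unsup"]))
                    xprime = apply_to_image(spec, xu).pixels
                    probs_u, leaves = network.forward(
                        student, xprime, training=True,
                        rng=rngs["dropout_unsup"], requires_grad=True,
                        leaves=leaves)
                    parts["ltc"] = consistency_mse(probs_u, target)
                    record["ltc"] = parts["ltc"].item()
                elif strategy == "STnoTC":
                    target = network.predict(teacher, xu, training=True,
                                             rng=rngs["dropout_unsup"])
                    probs_u, leaves = network.forward(
                        student, xu.pixels, training=True,
                        rng=rngs["dropout_unsup"], requires_grad=True,
                        leaves=leaves)
                    parts["lst"] = consistency_mse(probs_u, target)
                    record["lst"] = parts["lst"].item()
                else:  # STTC: student sees TF(xu), teacher sees xu.
                    # The perturbation here is the transform itself, so the
                    # teacher runs without dropout and its warped prediction
                    # is a deterministic target.
                    spec = sample_transform(rngs["aug_unlabeled"],
                                            augment_cfg, dim)
                    target = apply_to_map(spec, network.predict(
                        teacher, xu, training=False))
                    xprime = apply_to_image(spec, xu).pixels
                    probs_u, leaves = network.forward(
                        student, xprime, training=True,
                        rng=rngs["dropout_unsup"], requires_grad=True,
                        leaves=leaves)
                    parts["lst"] = consistency_mse(probs_u, target)
                    record["lst"] = parts["lst"].item()

            variant, parts_full = _variant_for(strategy, pl_mode, parts,
                                               unsup_active)
            total = compose_total_loss(variant, parts_full, weights)
            record["total"] = total.item()
            if not math.isfinite(record["total"]):
                raise RuntimeError(
                    f"divergent loss at iteration {i}: {record}")
            total.backward()
            grads = {k: t.grad for k, t in leaves.items()}
            optimizer.step(student.params, grads, lr)
            student.iteration = i + 1

            if is_st and teacher is not None:
                teacher = ema_update(teacher, student, schedule.alpha_ema)
                state.teacher = teacher

            state.iteration = i + 1
            if log_fh and i % log_every == 0:
                log_fh.write(json.dumps(record) + "\n")
            if on_iteration is not None:
                on_iteration(state, record)
    finally:
        if log_fh:
            log_fh.close()
    return student


def _variant_for(strategy: str, pl_mode: bool, parts: dict,
                 unsup_active: bool):
    """Map a strategy/stage to its loss variant, padding inactive terms."""
    cons_key = "ltc" if strategy == "TC" else "lst"
    if strategy == "SV":
        if pl_mode:
            return "PL", {"lpl": 0.0, **parts}
        return "TC", {**parts, "ltc": 0.0}   # supervised reduction: λ-term is 0
    if pl_mode:
        full = {"lpl": 0.0, **parts}
        full.setdefault("lst", 0.0)
        return "CASCADE", full
    full = {**parts}
    full.setdefault(cons_key, 0.0)
    return ("TC", full) if strategy == "TC" else ("ST", full)
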