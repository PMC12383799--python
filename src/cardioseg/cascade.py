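"""Pseudo-label generation and multi-stage training orchestration.

Ten method variants are supported: the four single-stage strategies (SV,
TC, STnoTC, STTC) and six two-stage pseudo-label pipelines
(SV-PL-SV, TC-PL-SV, STTC-PL-SV, SV-PL-STTC, STnoTC-PL-STnoTC and the
proposed STTC-PL-STTC cascade).  A two-stage run trains stage 1, infers
one pseudo-label for *every* member of the unlabeled pool (no filtering
or selection), assembles the stage-2 dataset in which ground truth labels
shadow pseudo-labels, and trains a second model from scratch with freshly
initialized weights.  Stage seeds are derived from the master seed so
"randomly initialized" stays reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import network
from .io_preprocess import DatasetSplit, LabelMap
from .losses import LossWeights
from .network import ModelParams
from .trainers import ConfigurationError, ScheduleConfig, train_stage

__all__ = ["PseudoLabelSet", "VariantPlan", "VariantResult", "LEGAL_VARIANTS",
           "infer_pseudolabels", "assemble_pl_dataset", "run_variant"]

LEGAL_VARIANTS = (
    "SV", "TC", "STnoTC", "STTC",
    "SV-PL-SV", "TC-PL-SV", "STTC-PL-SV", "SV-PL-STTC",
    "STnoTC-PL-STnoTC", "STTC-PL-STTC",
)

# per-strategy initial learning rates (supervised/TC vs student-teacher)
DEFAULT_LR = {"SV": 1e-4, "TC": 1e-4, "STnoTC": 5e-5, "STTC": 5e-5}


@dataclass
class PseudoLabelSet:
    """Exactly one pseudo-label per unlabeled sample, keyed by sample id."""

    entries: Dict[str, LabelMap]
    source_model: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)


@dataclass
class VariantPlan:
    """Stage strategies and loss weights of one method variant."""

    stage1: str
    stage2: Optional[str] = None
    weights_stage1: LossWeights = field(default_factory=LossWeights)
    weights_stage2: LossWeights = field(default_factory=LossWeights)

    @property
    def name(self) -> str:
        return self.stage1 if self.stage2 is None \
            else f"{self.stage1}-PL-{self.stage2}"

    @classmethod
    def from_name(cls, name: str) -> "VariantPlan":
        canon = name.replace("−", "-").strip()
        lookup = {v.lower(): v for v in LEGAL_VARIANTS}
        if canon.lower() not in lookup:
            raise ValueError(
                f"unknown variant {name!r}; legal: {LEGAL_VARIANTS}")
        canon = lookup[canon.lower()]
        parts = canon.split("-PL-")
        stage1 = parts[0]
        stage2 = parts[1] if len(parts) == 2 else None
        return cls(stage1, stage2)


@dataclass
class VariantResult:
    """Trained models plus intermediate artifacts of one variant run."""

    plan: VariantPlan
    final_model: ModelParams
    stage1_model: Optional[ModelParams] = None
    pseudolabels: Optional[PseudoLabelSet] = None
    artifact_paths: Dict[str, str] = field(default_factory=dict)


def infer_pseudolabels(m: ModelParams, unlabeled) -> PseudoLabelSet:
    """Argmax pseudo-labels for every unlabeled image (dropout disabled).

    No filtering or confidence selection is applied: each member of Xu
    receives exactly one pseudo-label.  Probability ties resolve to the
    lowest class index, deterministically.
    """
    unlabeled = list(unlabeled)
    if not unlabeled:
        raise ConfigurationError("unlabeled set is empty")
    entries = {}
    for img in unlabeled:
        probs = network.predict(m, img, training=False)
        entries[img.sample_id] = LabelMap(
            np.argmax(probs, axis=0).astype(np.int32), m.num_classes)
    meta = {"dim": m.dim, "num_classes": m.num_classes,
            "iteration": m.iteration, "seed": m.seed}
    return PseudoLabelSet(entries, source_model=meta)


def assemble_pl_dataset(split: DatasetSplit, pl: PseudoLabelSet) -> DatasetSplit:
    """Stage-2 split: every unlabeled image becomes labeled.

    Ground truth wins over pseudo-labels for originally labeled samples;
    the remaining pool members carry their pseudo-label and are flagged
    ``"pl"`` so stage-2 training can draw one ground-truth-labeled and one
    pseudo-labeled sample per iteration.  The unlabeled pool (Xfull,
    labels ignored) is kept for cascade consistency draws.
    """
    missing = [img.sample_id for img in split.unlabeled
               if img.sample_id not in pl.entries]
    if missing:
        raise ValueError(f"pseudo-labels missing for {len(missing)} samples "
                         f"(e.g. {missing[:3]})")
    gt_ids = {img.sample_id for img, _ in split.labeled}
    labeled = list(split.labeled)
    origin = ["gt"] * len(labeled)
    for img in split.unlabeled:
        if img.sample_id in gt_ids:
            continue
        labeled.append((img, pl.entries[img.sample_id]))
        origin.append("pl")
    return DatasetSplit(labeled=labeled, unlabeled=list(split.unlabeled),
                        fold_id=split.fold_id, labeled_origin=origin)


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0]
               & 0x7FFFFFFF)


def run_variant(plan, split: DatasetSplit, schedule: ScheduleConfig,
                seed: int, *, dim: int = 2,
                num_classes: Optional[int] = None, base_channels: int = 64,
                dropout_rate: float = 0.1, augment_cfg=None,
                lr_overrides: Optional[Dict[str, float]] = None,
                out_dir=None, on_iteration=None) -> VariantResult:
    """Execute one method variant end to end.

    Single-stage plans train once.  Pseudo-label plans train stage 1,
    infer pseudo-labels over the full unlabeled pool, and train stage 2
    from scratch with a stage seed derived from the master seed (so the
    two stages never share weights).  Initial learning rates follow the
    per-strategy presets unless overridden.  With ``out_dir`` the stage
    checkpoints, the pseudo-label set and a manifest are persisted.
    """
    if isinstance(plan, str):
        plan = VariantPlan.from_name(plan)
    if plan.name not in LEGAL_VARIANTS:
        raise ValueError(f"illegal variant plan {plan.name!r}")
    lrs = dict(DEFAULT_LR)
    lrs.update(lr_overrides or {})
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}

    def stage_schedule(strategy: str, stage_uses_pl: bool) -> ScheduleConfig:
        # pseudo-label (stage-2 supervised) training follows the ST rate
        lr0 = lrs["STnoTC"] if stage_uses_pl and strategy == "SV" \
            else lrs[strategy]
        return dataclasses.replace(schedule, lr0=lr0)

    common = dict(dim=dim, num_classes=num_classes,
                  base_channels=base_channels, dropout_rate=dropout_rate,
                  augment_cfg=augment_cfg, on_iteration=on_iteration)

    model1 = train_stage(plan.stage1, split,
                         stage_schedule(plan.stage1, False),
                         plan.weights_stage1, _stage_seed(seed, 1), **common)
    if out_dir is not None:
        artifacts["stage1"] = str(network.save_checkpoint(
            model1, out_dir / "stage1.npz"))

    if plan.stage2 is None:
        _write_manifest(out_dir, plan, seed, artifacts)
        return VariantResult(plan, model1, artifact_paths=artifacts)

    pl = infer_pseudolabels(model1, split.unlabeled)
    split2 = assemble_pl_dataset(split, pl)
    if out_dir is not None:
        artifacts["pseudolabels"] = str(_save_pseudolabels(
            pl, out_dir / "pseudolabels.npz"))

    model2 = train_stage(plan.stage2, split2,
                         stage_schedule(plan.stage2, True),
                         plan.weights_stage2, _stage_seed(seed, 2), **common)
    if out_dir is not None:
        artifacts["stage2"] = str(network.save_checkpoint(
            model2, out_dir / "stage2.npz"))
    _write_manifest(out_dir, plan, seed, artifacts)
    return VariantResult(plan, model2, stage1_model=model1, pseudolabels=pl,
                         artifact_paths=artifacts)


def _save_pseudolabels(pl: PseudoLabelSet, path: Path) -> Path:
    arrays = {k: v.classes for k, v in pl.entries.items()}
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(
        {"source_model": pl.source_model, "n_entries": len(pl)}, indent=2))
    return path


def _write_manifest(out_dir: Optional[Path], plan: VariantPlan, seed: int,
                    artifacts: Dict[str, str]) -> None:
    if out_dir is None:
        return
    manifest = {"variant": plan.name, "seed": seed, "artifacts": artifacts}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
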