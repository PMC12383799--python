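import json

import numpy as np
import pytest

from cardioseg import (ScheduleConfig, VariantPlan,
                       assemble_pl_dataset, build_unet, infer_pseudolabels,
                       load_checkpoint, run_variant)
from cardioseg.cascade import LEGAL_VARIANTS
from cardioseg.trainers import ConfigurationError


def tiny_schedule(n=16):
    return ScheduleConfig(total_iterations=n, lr0=1e-3, alpha_ema=0.9)


class TestVariantPlan:
    def test_all_legal_names_parse(self):
        for name in LEGAL_VARIANTS:
            plan = VariantPlan.from_name(name)
            assert plan.name == name

    def test_case_and_unicode_minus_tolerated(self):
        assert VariantPlan.from_name("sttc-pl-sttc").name == "STTC-PL-STTC"
        assert VariantPlan.from_name("SV−PL−SV").name == "SV-PL-SV"

    def test_illegal_names_rejected(self):
        for bad in ("TC-PL-TC", "SV-PL", "STTC-PL-TC", ""):
            with pytest.raises(ValueError):
                VariantPlan.from_name(bad)


class TestPseudoLabels:
    def test_one_label_per_unlabeled_sample(self, tiny_split):
        split, _ = tiny_split
        m = build_unet(2, 4, seed=0, base_channels=4)
        pl = infer_pseudolabels(m, split.unlabeled)
        assert len(pl) == len(split.unlabeled)
        ids = {img.sample_id for img in split.unlabeled}
        assert set(pl.entries) == ids

    def test_deterministic_and_grid_matched(self, tiny_split):
        split, _ = tiny_split
        m = build_unet(2, 4, seed=0, base_channels=4)
        a = infer_pseudolabels(m, split.unlabeled)
        b = infer_pseudolabels(m, split.unlabeled)
        for sid in a.entries:
            np.testing.assert_array_equal(a.entries[sid].classes,
                                          b.entries[sid].classes)
        img = split.unlabeled[0]
        assert a.entries[img.sample_id].shape == img.shape

    def test_empty_set_rejected(self):
        m = build_unet(2, 2, seed=0, base_channels=2)
        with pytest.raises(ConfigurationError):
            infer_pseudolabels(m, [])

    def test_tie_breaks_to_lowest_class(self, monkeypatch, tiny_split):
        split, _ = tiny_split
        m = build_unet(2, 4, seed=0, base_channels=4)
        from cardioseg import cascade as cas

        def tied_predict(model, img, training=False, rng=None):
            shape = img.shape if hasattr(img, "shape") else img.shape
            return np.full((model.num_classes,) + tuple(shape),
                           1.0 / model.num_classes)

        monkeypatch.setattr(cas.network, "predict", tied_predict)
        pl = infer_pseudolabels(m, split.unlabeled[:2])
        for lab in pl.entries.values():
            assert (lab.classes == 0).all()


class TestAssemble:
    def test_stage2_pool_sizes_and_origins(self, tiny_split):
        split, _ = tiny_split
        m = build_unet(2, 4, seed=0, base_channels=4)
        pl = infer_pseudolabels(m, split.unlabeled)
        merged = assemble_pl_dataset(split, pl)
        assert len(merged.labeled) == len(split.unlabeled)
        assert len(merged.gt_indices) == len(split.labeled)
        assert len(merged.pl_indices) == \
            len(split.unlabeled) - len(split.labeled)

    def test_ground_truth_shadows_pseudolabels(self, tiny_split):
        split, _ = tiny_split
        m = build_unet(2, 4, seed=0, base_channels=4)
        pl = infer_pseudolabels(m, split.unlabeled)
        merged = assemble_pl_dataset(split, pl)
        gt_by_id = {img.sample_id: lab for img, lab in split.labeled}
        for i in merged.gt_indices:
            img, lab = merged.labeled[i]
            np.testing.assert_array_equal(lab.classes,
                                          gt_by_id[img.sample_id].classes)

    def test_every_pair_grid_consistent(self, tiny_split):
        split, _ = tiny_split
        m = build_unet(2, 4, seed=0, base_channels=4)
        merged = assemble_pl_dataset(split,
                                     infer_pseudolabels(m, split.unlabeled))
        assert all(img.shape == lab.shape for img, lab in merged.labeled)

    def test_coverage_gap_rejected(self, tiny_split):
        split, _ = tiny_split
        m = build_unet(2, 4, seed=0, base_channels=4)
        pl = infer_pseudolabels(m, split.unlabeled[:-1])
        with pytest.raises(ValueError):
            assemble_pl_dataset(split, pl)


class TestRunVariant:
    def test_single_stage_no_pl_artifacts(self, tiny_split, tmp_path):
        split, _ = tiny_split
        res = run_variant("SV", split, tiny_schedule(), seed=3, dim=2,
                          base_channels=4, out_dir=tmp_path / "sv")
        assert res.pseudolabels is None
        assert set(res.artifact_paths) == {"stage1"}
        manifest = json.loads((tmp_path / "sv" / "manifest.json").read_text())
        assert manifest["variant"] == "SV"

    def test_cascade_emits_all_artifacts(self, tiny_split, tmp_path):
        split, _ = tiny_split
        res = run_variant("STTC-PL-STTC", split, tiny_schedule(), seed=3,
                          dim=2, base_channels=4, out_dir=tmp_path / "c")
        assert set(res.artifact_paths) == {"stage1", "pseudolabels", "stage2"}
        assert len(res.pseudolabels) == len(split.unlabeled)
        stage2 = load_checkpoint(res.artifact_paths["stage2"])
        assert stage2.num_classes == 4

    def test_stage2_initialized_from_scratch(self, tiny_split):
        split, _ = tiny_split
        res = run_variant("SV-PL-SV", split, tiny_schedule(), seed=3, dim=2,
                          base_channels=4)
        k = "enc1.conv1.w"
        assert not np.array_equal(res.stage1_model.params[k],
                                  res.final_model.params[k])
        assert res.stage1_model.seed != res.final_model.seed

    def test_rerun_bit_identical(self, tiny_split):
        split, _ = tiny_split
        a = run_variant("STTC-PL-SV", split, tiny_schedule(), seed=11, dim=2,
                        base_channels=4)
        b = run_variant("STTC-PL-SV", split, tiny_schedule(), seed=11, dim=2,
                        base_channels=4)
        for sid in a.pseudolabels.entries:
            np.testing.assert_array_equal(a.pseudolabels.entries[sid].classes,
                                          b.pseudolabels.entries[sid].classes)
        for k in a.final_model.params:
            np.testing.assert_array_equal(a.final_model.params[k],
                                          b.final_model.params[k])

    def test_stage2_draw_origins_balanced(self, tiny_split):
        """Each stage-2 iteration draws one ground-truth-labeled and one
        pseudo-labeled sample."""
        split, _ = tiny_split
        records = []
        run_variant("SV-PL-SV", split, tiny_schedule(12), seed=3, dim=2,
                    base_channels=4,
                    on_iteration=lambda st, rec: records.append(rec))
        stage2 = [r for r in records if "pl_index" in r]
        assert len(stage2) == 12
        m = build_unet(2, 4, seed=0, base_channels=4)
        merged = assemble_pl_dataset(split,
                                     infer_pseudolabels(m, split.unlabeled))
        gt = set(merged.gt_indices)
        plset = set(merged.pl_indices)
        for r in stage2:
            assert r["labeled_index"] in gt
            assert r["pl_index"] in plset
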