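import collections

import numpy as np
import pytest

from cardioseg import (DatasetSplit, LossWeights, ScheduleConfig, build_unet,
                       ema_update, lr_at_iteration, sample_training_pair,
                       train_stage)
from cardioseg.trainers import ConfigurationError


def short_schedule(n=40, **kw):
    kw.setdefault("lr0", 1e-3)
    kw.setdefault("alpha_ema", 0.95)
    return ScheduleConfig(total_iterations=n, **kw)


class TestEMA:
    def test_alpha_extremes(self):
        t = build_unet(2, 3, seed=0, base_channels=2)
        s = build_unet(2, 3, seed=1, base_channels=2)
        unchanged = ema_update(t, s, 1.0)
        copied = ema_update(t, s, 0.0)
        k = next(iter(t.params))
        np.testing.assert_array_equal(unchanged.params[k], t.params[k])
        np.testing.assert_array_equal(copied.params[k], s.params[k])

    def test_recursion_value(self):
        t = build_unet(2, 2, seed=0, base_channels=2)
        s = build_unet(2, 2, seed=0, base_channels=2)
        for k in t.params:
            t.params[k][:] = 0.0
            s.params[k][:] = 1.0
        out = ema_update(t, s, 0.999)
        k = next(iter(t.params))
        np.testing.assert_allclose(out.params[k], 0.001, rtol=1e-5)

    def test_closed_form_after_many_steps(self, rng):
        """θT^n = αⁿθT⁰ + (1-α)Σ α^{n-k} θS^k, verified elementwise."""
        alpha, n = 0.97, 200
        teacher0 = rng.standard_normal(5)
        students = [rng.standard_normal(5) for _ in range(n)]
        from cardioseg.network import ModelParams
        t = ModelParams({"w": teacher0.copy()}, 2, 2, 1)
        for sk in students:
            t = ema_update(t, ModelParams({"w": sk}, 2, 2, 1), alpha)
        expect = alpha ** n * teacher0
        for k, sk in enumerate(students, start=1):
            expect = expect + (1 - alpha) * alpha ** (n - k) * sk
        np.testing.assert_allclose(t.params["w"], expect, rtol=1e-10)


class TestSchedule:
    def test_endpoints_and_monotonicity(self):
        cfg = ScheduleConfig(total_iterations=100, lr0=1e-4, decay_rate=0.1)
        assert lr_at_iteration(0, 100, cfg) == pytest.approx(1e-4)
        assert lr_at_iteration(100, 100, cfg) == pytest.approx(1e-5)
        lrs = [lr_at_iteration(i, 100, cfg) for i in range(101)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_zero_total_rejected(self):
        cfg = ScheduleConfig(total_iterations=1)
        with pytest.raises(ValueError):
            lr_at_iteration(0, 0, cfg)

    def test_warmup_ramps_then_decays(self):
        cfg = ScheduleConfig(total_iterations=100, lr0=1e-3,
                             warmup_fraction=0.1)
        assert lr_at_iteration(0, 100, cfg) < lr_at_iteration(9, 100, cfg)
        assert lr_at_iteration(10, 100, cfg) == \
            pytest.approx(1e-3 * 0.1 ** 0.1)


class TestSampling:
    def test_uniform_coverage(self, tiny_split):
        split, _ = tiny_split
        rng = np.random.default_rng(0)
        counts = collections.Counter(
            sample_training_pair(split, rng)[0][0].sample_id
            for _ in range(600))
        assert len(counts) == len(split.labeled)
        # crude uniformity: no sample dominates
        assert max(counts.values()) < 4 * min(counts.values())

    def test_reproducible_draws(self, tiny_split):
        split, _ = tiny_split
        a = [sample_training_pair(split, np.random.default_rng(3))[1].sample_id
             for _ in range(5)]
        b = []
        rng = np.random.default_rng(3)
        for _ in range(5):
            b.append(sample_training_pair(split, rng)[1].sample_id)
        assert a[0] == b[0]

    def test_empty_pools_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_training_pair(DatasetSplit([], []), np.random.default_rng(0))


class TestTrainStage:
    def test_supervised_descent(self, tiny_split):
        split, _ = tiny_split
        losses = []
        train_stage("SV", split, short_schedule(150), LossWeights(), seed=5,
                    dim=2, base_channels=8,
                    on_iteration=lambda st, rec: losses.append(rec["lsv"]))
        assert np.mean(losses[-20:]) < np.mean(losses[:20])

    def test_unsupervised_weight_zero_before_switch(self, tiny_split):
        split, _ = tiny_split
        recs = []
        train_stage("STTC", split, short_schedule(30), LossWeights(), seed=5,
                    dim=2, base_channels=4,
                    on_iteration=lambda st, rec: recs.append(rec))
        switch = short_schedule(30).switch_iteration
        for rec in recs[:switch]:
            assert rec["consistency_weight"] == 0.0
            assert "lst" not in rec
        assert any("lst" in rec for rec in recs[switch:])

    def test_teacher_follows_ema_recursion(self, tiny_split):
        """The teacher equals the closed-form EMA of the student trajectory
        replayed offline from the logged student parameters."""
        split, _ = tiny_split
        sched = short_schedule(24, alpha_ema=0.9)
        students, teachers = [], []

        def record(state, rec):
            students.append({k: v.copy()
                             for k, v in state.student.params.items()})
            teachers.append(None if state.teacher is None else
                            {k: v.copy()
                             for k, v in state.teacher.params.items()})

        train_stage("STnoTC", split, sched, LossWeights(), seed=5,
                    dim=2, base_channels=4, on_iteration=record)
        switch = sched.switch_iteration
        assert all(t is None for t in teachers[:switch - 1])
        # teacher at the switch iteration: copy of pre-update student,
        # then one EMA step with the post-update student
        expect = {k: v.copy() for k, v in students[switch - 1].items()}
        for i in range(switch, len(students)):
            expect = {k: 0.9 * expect[k] + 0.1 * students[i][k]
                      for k in expect}
            for k in expect:
                np.testing.assert_allclose(teachers[i][k], expect[k],
                                           rtol=1e-5, atol=1e-7)

    def test_divergence_aborts(self, tiny_split):
        split, _ = tiny_split
        sched = short_schedule(30, lr0=1e6)    # absurd rate forces non-finite
        with pytest.raises(RuntimeError):
            train_stage("SV", split, sched, LossWeights(), seed=5,
                        dim=2, base_channels=4)

    def test_unknown_strategy_rejected(self, tiny_split):
        split, _ = tiny_split
        with pytest.raises(ConfigurationError):
            train_stage("FOO", split, short_schedule(), LossWeights(), seed=1)

    def test_log_file_written(self, tiny_split, tmp_path):
        import json
        split, _ = tiny_split
        log = tmp_path / "log.jsonl"
        train_stage("SV", split, short_schedule(10), LossWeights(), seed=5,
                    dim=2, base_channels=4, log_path=log, log_every=2)
        lines = [json.loads(l) for l in log.read_text().splitlines()]
        assert len(lines) == 5
        assert {"iteration", "lr", "lsv", "total"} <= set(lines[0])


class TestReduction:
    @pytest.mark.parametrize("strategy", ["TC", "STnoTC", "STTC"])
    def test_zero_weight_no_unlabeled_reduces_to_sv(self, tiny_split,
                                                    strategy):
        """With zero consistency weight and an empty unlabeled pool the
        semi-supervised trainers reproduce SV training bit-identically."""
        split, _ = tiny_split
        bare = DatasetSplit(labeled=split.labeled, unlabeled=[])
        w0 = LossWeights(0.0, 0.0, 0.0)
        sched = short_schedule(30)
        sv = train_stage("SV", bare, sched, w0, seed=9, dim=2,
                         base_channels=4)
        other = train_stage(strategy, bare, sched, w0, seed=9, dim=2,
                            base_channels=4)
        for k in sv.params:
            np.testing.assert_array_equal(sv.params[k], other.params[k])
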