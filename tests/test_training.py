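"""Dice loss contracts, balancing, splitting, and the training loop."""

import numpy as np
import pandas as pd
import pytest

from thoraseg.annotations import TumorSizeStats
from thoraseg.networks import student_config, teacher_config
from thoraseg.phantoms import PhantomConfig, generate_cohort
from thoraseg.preprocess import PreprocessConfig
from thoraseg.training import (
    StudentSample,
    TrainConfig,
    balance_by_size,
    dice_loss,
    load_checkpoint,
    make_split,
    prepare_teacher_sample,
    save_checkpoint,
    train_student,
    train_teacher,
)

from conftest import grid


PRE = PreprocessConfig(teacher_patch=(32, 32, 32), lung_margin=4)
TINY_TEACHER = teacher_config(base_width=2)


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self, rng):
        g = (rng.random((6, 6, 6)) > 0.5).astype(float)
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_total_miss_near_one(self):
        g = np.zeros((6, 6, 6))
        g[1:3, 1:3, 1:3] = 1
        assert dice_loss(np.zeros_like(g), g) == pytest.approx(1.0, abs=1e-5)

    def test_half_overlap_closed_form(self):
        # prob 0.5 everywhere, |G| = N in a 2N-voxel volume:
        # loss = 1 - (N + eps)/(2N + eps) ~ 0.5
        n = 32
        g = np.zeros(2 * n)
        g[:n] = 1
        p = np.full(2 * n, 0.5)
        eps = 1e-5
        expected = 1 - (2 * 0.5 * n + eps) / (0.5 * 2 * n + n + eps)
        assert dice_loss(p, g, eps) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.5, abs=1e-6)

    def test_permutation_invariance(self, rng):
        p = rng.random(100)
        g = (rng.random(100) > 0.5).astype(float)
        perm = rng.permutation(100)
        assert dice_loss(p, g) == pytest.approx(dice_loss(p[perm], g[perm]))

    def test_misaligned_grids_rejected(self, rng):
        a = grid(rng.random((4, 4, 4)))
        b = grid(rng.random((4, 4, 4)), origin=(9, 9, 9))
        with pytest.raises(ValueError):
            dice_loss(a, b)


class TestBalanceBySize:
    @staticmethod
    def stats(vols):
        return [TumorSizeStats(volume_cm3=v, diameter_mm=0) for v in vols]

    def test_single_bin_unchanged(self):
        cases = list("abcd")
        out = balance_by_size(cases, self.stats([5.0, 5.0, 5.0, 5.0]))
        assert out == cases

    def test_rare_bin_replicated(self):
        # 8 cases in the dominant bins vs 2 in the rare bin -> x4
        vols = [1.0] * 8 + [100.0, 110.0]
        cases = [f"c{i}" for i in range(10)]
        out = balance_by_size(cases, self.stats(vols))
        counts = pd.Series(out).value_counts()
        assert counts["c8"] == counts["c9"] == 4

    def test_bins_within_one_replication_unit(self, rng):
        vols = rng.lognormal(1, 1, 40)
        cases = list(range(40))
        out = balance_by_size(cases, self.stats(list(vols)))
        edges = np.quantile(vols, [0.25, 0.5, 0.75])
        bins = np.searchsorted(edges, [vols[c] for c in out], side="left")
        counts = np.bincount(bins, minlength=4)
        orig = np.bincount(np.searchsorted(edges, vols, side="left"), minlength=4)
        assert counts.max() - counts.min() < max(orig.max(), 1) + orig.max()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            balance_by_size([], [])

    def test_deterministic_in_input_order(self, rng):
        vols = list(rng.lognormal(0, 1, 12))
        cases = list(range(12))
        assert balance_by_size(cases, self.stats(vols)) == balance_by_size(
            cases, self.stats(vols)
        )


class TestMakeSplit:
    def test_fifteen_percent_of_single_scan_patients(self):
        ids = [f"c{i}" for i in range(100)]
        spec = make_split(ids, ids, seed=0)
        assert len(spec.test) == 15
        assert sorted(spec.train + spec.val + spec.test) == sorted(ids)

    def test_multi_scan_patient_co_assigned(self):
        case_ids = [f"c{i}" for i in range(20)]
        patients = [f"p{i // 2}" for i in range(20)]  # 2 scans each
        spec = make_split(case_ids, patients, seed=3)
        for subset in (spec.train, spec.val, spec.test):
            pats = {patients[case_ids.index(c)] for c in subset}
            for other in (spec.train, spec.val, spec.test):
                if other is subset:
                    continue
                assert pats.isdisjoint(
                    {patients[case_ids.index(c)] for c in other}
                )

    def test_same_seed_identical_split(self):
        ids = [f"c{i}" for i in range(30)]
        a = make_split(ids, ids, seed=7)
        b = make_split(ids, ids, seed=7)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="3"):
            make_split(["a", "b"], ["a", "b"], seed=0)


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(PhantomConfig(), n_strong=2, n_weak=1, seed=42)


class TestTrainTeacherLoop:
    def test_zero_epochs_returns_initial_weights(self, tiny_cohort):
        from thoraseg.networks import build_teacher

        cfg = TrainConfig(lr=1e-2, virtual_batch=1, max_epochs=0, seed=5)
        ckpt = train_teacher(tiny_cohort.strong, "box", TINY_TEACHER, cfg, pre_cfg=PRE)
        init = build_teacher(TINY_TEACHER, seed=5)
        for a, b in zip(ckpt.state, init.state()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_loss_curves(self, tiny_cohort):
        cfg = TrainConfig(lr=1e-2, virtual_batch=1, max_epochs=3, seed=1)
        a = train_teacher(tiny_cohort.strong, "box", TINY_TEACHER, cfg, pre_cfg=PRE)
        b = train_teacher(tiny_cohort.strong, "box", TINY_TEACHER, cfg, pre_cfg=PRE)
        pd.testing.assert_frame_equal(a.log, b.log)
        for x, y in zip(a.state, b.state):
            np.testing.assert_array_equal(x, y)

    def test_empty_dataset_rejected(self):
        cfg = TrainConfig(max_epochs=1)
        with pytest.raises(ValueError, match="empty|at least"):
            train_teacher([], "box", TINY_TEACHER, cfg, pre_cfg=PRE)

    def test_loss_grouping_invariance_at_lr_zero(self, tiny_cohort):
        """With frozen weights the per-epoch loss is independent of the
        virtual-batch grouping."""
        losses = {}
        for vb in (1, 2):
            cfg = TrainConfig(lr=0.0, virtual_batch=vb, max_epochs=2, seed=9)
            ck = train_teacher(tiny_cohort.strong, "box", TINY_TEACHER, cfg, pre_cfg=PRE)
            losses[vb] = ck.log.train_loss.to_numpy()
        np.testing.assert_allclose(losses[1], losses[2], rtol=1e-6)

    def test_checkpoint_round_trip(self, tiny_cohort, tmp_path):
        cfg = TrainConfig(lr=1e-2, virtual_batch=1, max_epochs=1, seed=2)
        ck = train_teacher(tiny_cohort.strong, "box", TINY_TEACHER, cfg, pre_cfg=PRE)
        save_checkpoint(ck, tmp_path / "t.npz")
        back = load_checkpoint(tmp_path / "t.npz")
        assert back.guidance_kind == "box" and back.arch == "teacher"
        for a, b in zip(ck.state, back.state):
            np.testing.assert_array_equal(a, b)
        net = back.build()
        s = prepare_teacher_sample(tiny_cohort.strong[0], "box", PRE)
        out = net.predict(s.inputs)
        assert out.shape == (1,) + s.inputs.shape[1:]


def _toy_student_samples(rng, n, shape=(16, 16, 16)):
    out = []
    for i in range(n):
        img = rng.standard_normal((1,) + shape).astype(np.float32)
        tgt = np.zeros((1,) + shape, np.float32)
        tgt[0, 4:8, 4:8, 4:8] = 1
        out.append(
            StudentSample(
                case_id=f"s{i}", inputs=img, target=tgt, tumor_volume_cm3=float(i)
            )
        )
    return out


class TestTrainStudentLoop:
    def test_baseline_is_degenerate_student(self, rng):
        """Training with no pseudo cases follows the identical code path
        and reproduces the strong-only configuration bit for bit."""
        strong = _toy_student_samples(rng, 3)
        cfg = TrainConfig(lr=1e-2, virtual_batch=2, max_epochs=2, seed=4, balance=False)
        a = train_student(strong, [], "so", student_config(base_width=2), cfg)
        b = train_student(strong, [], "so", student_config(base_width=2), cfg)
        for x, y in zip(a.state, b.state):
            np.testing.assert_array_equal(x, y)

    def test_do_student_logs_two_decreasing_head_losses(self, rng):
        strong = _toy_student_samples(rng, 2)
        cfg = TrainConfig(lr=1e-2, virtual_batch=1, max_epochs=12, seed=4, balance=False)
        ck = train_student(strong, [], "do", student_config(base_width=2, dual=True), cfg)
        assert {"head0_loss", "head1_loss"} <= set(ck.log.columns)
        for col in ("head0_loss", "head1_loss"):
            series = ck.log[col]
            assert series.iloc[-1] < series.iloc[0]

    def test_trained_teacher_uses_guidance_channel(self, tiny_cohort):
        """All-zero vs all-one guidance on a trained teacher must change
        the prediction: the guidance channel is not ignored."""
        cfg = TrainConfig(lr=1e-2, virtual_batch=1, max_epochs=5, seed=0)
        ck = train_teacher(tiny_cohort.strong, "box", TINY_TEACHER, cfg, pre_cfg=PRE)
        net = ck.build()
        s = prepare_teacher_sample(tiny_cohort.strong[0], "box", PRE)
        img = s.inputs[0]
        zero = net.predict(np.stack([img, np.zeros_like(img)]))
        one = net.predict(np.stack([img, np.ones_like(img)]))
        assert not np.array_equal(zero, one)

    def test_invalid_arch_rejected(self, rng):
        with pytest.raises(ValueError, match="arch"):
            train_student(
                _toy_student_samples(rng, 1), [], "foo",
                student_config(base_width=2), TrainConfig(max_epochs=1),
            )
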