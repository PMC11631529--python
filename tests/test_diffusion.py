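"""Schedule, target assignment, loss, denoising steps and training ops."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diffsplit import (
    BackboneSpec,
    ConfigError,
    DiffusionTrainConfig,
    InstanceLabelSet,
    SemanticMask,
    SplitFieldPair,
    SplitTargets,
    assign_split_targets,
    blend_training_fields,
    bootstrap_targets,
    denoise_step,
    make_schedule,
    make_training_sample,
    run_denoising_chain,
    sample_noise_fields,
    split_loss,
    train_split_model,
)
from diffsplit.diffusion import _stack_inputs
from diffsplit.oracle import ConstantSplitModel

from conftest import make_mask


class TestSchedule:
    def test_reference_grid_at_n100(self):
        s = make_schedule(100)
        i = np.arange(101)
        np.testing.assert_allclose(s.t, 10.0 ** (i / 10.0 - 10.0), rtol=1e-12)
        assert s.t[0] == pytest.approx(1e-10)
        assert s.t[100] == 1.0
        assert s.w[99] == 1.0

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(2, 1000))
    def test_invariants_any_n(self, n):
        s = make_schedule(n)
        assert np.all(np.diff(s.t) > 0)
        assert s.t[-1] == 1.0
        assert np.all(s.w > 0) and np.all(s.w <= 1)
        assert s.w[-1] == 1.0
        # weights follow from the time grid
        np.testing.assert_allclose(
            s.w[:-1], (s.t[1:-1] - s.t[:-2]) / (1 - s.t[:-2]), rtol=1e-12
        )

    def test_too_few_steps_rejected(self):
        with pytest.raises(ConfigError):
            make_schedule(1)


class TestNoiseFields:
    def test_deterministic_given_seed(self, overlap_scene):
        S = overlap_scene.semantic
        a = sample_noise_fields(S.shape, S, seed=9)
        b = sample_noise_fields(S.shape, S, seed=9)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.B, b.B)

    def test_background_masked_to_zero(self, overlap_scene):
        S = overlap_scene.semantic
        f = sample_noise_fields(S.shape, S, seed=1)
        bg = ~S.binary
        assert np.all(f.A[bg] == 0) and np.all(f.B[bg] == 0)

    def test_all_background_gives_zero_fields(self):
        S = SemanticMask(np.zeros((16, 16), dtype=np.float32))
        f = sample_noise_fields((16, 16), S, seed=0)
        assert not f.A.any() and not f.B.any()

    def test_empirical_mean_on_large_support(self):
        S = SemanticMask(np.ones((100, 100), dtype=np.float32))
        f = sample_noise_fields((100, 100), S, mean=0.5, sigma=0.25, seed=4)
        assert abs(float(f.A.mean()) - 0.5) < 0.02  # clipping bias tolerated

    def test_nonpositive_sigma_rejected(self, overlap_scene):
        with pytest.raises(ConfigError):
            sample_noise_fields((16, 16), overlap_scene.semantic, sigma=0.0)


class TestAssignment:
    def test_sum_comparison_by_hand(self):
        m = make_mask((4, 4), [(0, 0), (0, 1)])
        a = np.zeros((4, 4), np.float32)
        b = np.zeros((4, 4), np.float32)
        a[0, 0], a[0, 1] = 0.9, 0.8
        b[0, 0], b[0, 1] = 0.1, 0.2
        t = assign_split_targets(SplitFieldPair(a, b), InstanceLabelSet((m,)))
        assert t.assignment == ("A",)
        np.testing.assert_array_equal(t.MA, m.pixels.astype(np.float32))
        assert not t.MB.any()

    def test_exact_tie_goes_to_a(self):
        m = make_mask((4, 4), [(1, 1), (2, 2)])
        a = np.full((4, 4), 0.3, np.float32)
        b = np.full((4, 4), 0.3, np.float32)
        t = assign_split_targets(SplitFieldPair(a, b), InstanceLabelSet((m,)))
        assert t.assignment == ("A",)

    def test_all_zero_fields_assign_everything_to_a(self, overlap_scene):
        z = np.zeros((16, 16), np.float32)
        t = assign_split_targets(SplitFieldPair(z, z.copy()), overlap_scene.labels)
        assert t.assignment == ("A", "A")

    def test_empty_label_set_gives_empty_targets(self):
        z = np.zeros((8, 8), np.float32)
        t = assign_split_targets(SplitFieldPair(z, z.copy()), InstanceLabelSet(()))
        assert t.assignment == ()
        assert not t.MA.any() and not t.MB.any()

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_each_mask_in_exactly_one_split_and_union_preserved(self, seed):
        from conftest import random_label_set

        rng = np.random.default_rng(seed)
        labels = random_label_set(rng, n_masks=int(rng.integers(1, 5)))
        h, w = labels.shape
        fields = SplitFieldPair(
            rng.random((h, w), dtype=np.float32), rng.random((h, w), dtype=np.float32)
        )
        t = assign_split_targets(fields, labels)
        ma, mb = t.MA.astype(bool), t.MB.astype(bool)
        np.testing.assert_array_equal(ma | mb, labels.union())
        for m, side in zip(labels, t.assignment):
            target = ma if side == "A" else mb
            assert np.all(target[m.pixels])


class TestBlendAndLoss:
    def test_blend_endpoints_and_midpoint(self, overlap_scene):
        S = overlap_scene.semantic
        noise = sample_noise_fields(S.shape, S, seed=2)
        targets = assign_split_targets(noise, overlap_scene.labels)
        np.testing.assert_array_equal(blend_training_fields(noise, targets, 0.0).A, noise.A)
        np.testing.assert_array_equal(blend_training_fields(noise, targets, 1.0).A, targets.MA)
        mixed = blend_training_fields(noise, targets, 0.5)
        # hand value: noise 0.4, target 1 -> 0.7
        i, j = np.argwhere(targets.MA > 0)[0]
        expect = 0.5 * noise.A[i, j] + 0.5
        assert mixed.A[i, j] == pytest.approx(expect)
        with pytest.raises(ConfigError):
            blend_training_fields(noise, targets, 1.5)

    def test_uniform_half_prediction_closed_form(self):
        s_px = np.zeros((20, 20), np.float32)
        s_px[3:8, 3:11] = 1.0  # k = 40 foreground pixels
        S = SemanticMask(s_px)
        k = int(s_px.sum())
        targets = SplitTargets(MA=s_px.copy(), MB=np.zeros_like(s_px))
        pred = np.full((20, 20), 0.5, np.float32)
        loss = split_loss(pred, pred, targets, S)
        assert loss == pytest.approx(2 * k * math.log(2), rel=1e-6)

    def test_background_predictions_do_not_contribute(self, rng):
        s_px = np.zeros((16, 16), np.float32)
        s_px[2:6, 2:6] = 1.0
        S = SemanticMask(s_px)
        targets = SplitTargets(MA=s_px.copy(), MB=np.zeros_like(s_px))
        base = np.full((16, 16), 0.5, np.float32)
        l0 = split_loss(base, base, targets, S)
        for _ in range(5):
            noisy = base.copy()
            noisy[s_px == 0] = rng.random(((s_px == 0).sum(),))
            assert split_loss(noisy, noisy, targets, S) == pytest.approx(l0)

    def test_perfect_prediction_near_zero_and_saturation_safe(self):
        s_px = np.ones((8, 8), np.float32)
        S = SemanticMask(s_px)
        targets = SplitTargets(MA=s_px.copy(), MB=np.zeros_like(s_px))
        loss = split_loss(s_px, np.zeros_like(s_px), targets, S)
        assert np.isfinite(loss)
        assert loss < 2 * 64 * 2e-7  # clamp-epsilon bound


class TestDenoiseStep:
    def test_w_one_returns_masked_model_output(self, overlap_scene):
        S = overlap_scene.semantic
        model = ConstantSplitModel(0.7, 0.2)
        f0 = sample_noise_fields(S.shape, S, seed=1)
        f1 = denoise_step(model, overlap_scene.image, S, f0, 1.0)
        np.testing.assert_allclose(f1.A, S.pixels * 0.7, rtol=1e-6)
        np.testing.assert_allclose(f1.B, S.pixels * 0.2, rtol=1e-6)
        assert f1.step_index == 1

    def test_w_zero_is_identity_on_foreground(self, overlap_scene):
        S = overlap_scene.semantic
        model = ConstantSplitModel(0.9, 0.9)
        f0 = sample_noise_fields(S.shape, S, seed=1)
        f1 = denoise_step(model, overlap_scene.image, S, f0, 0.0)
        np.testing.assert_allclose(f1.A, S.pixels * f0.A, rtol=1e-6)

    def test_background_always_zero(self, overlap_scene):
        S = overlap_scene.semantic
        model = ConstantSplitModel(1.0, 1.0)
        f = sample_noise_fields(S.shape, S, seed=3)
        for w in (0.0, 0.3, 1.0):
            f2 = denoise_step(model, overlap_scene.image, S, f, w)
            assert np.all(f2.A[~S.binary] == 0)


class TestChain:
    def test_identical_seeds_identical_outputs(self, overlap_scene):
        S = overlap_scene.semantic
        sched = make_schedule(4)
        model = ConstantSplitModel(0.8, 0.3)
        a = run_denoising_chain(model, overlap_scene.image, S, sched, seed=5)
        b = run_denoising_chain(model, overlap_scene.image, S, sched, seed=5)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.B, b.B)

    def test_constant_model_forces_final_state(self, overlap_scene):
        S = overlap_scene.semantic
        sched = make_schedule(6)
        model = ConstantSplitModel(1.0, 0.0)
        f = run_denoising_chain(model, overlap_scene.image, S, sched, seed=0)
        np.testing.assert_allclose(f.A, S.pixels, rtol=1e-6)
        assert not f.B.any()

    def test_chain_equals_manual_fold_of_steps(self, overlap_scene):
        S = overlap_scene.semantic
        sched = make_schedule(2)
        model = ConstantSplitModel(0.6, 0.4)
        chain = run_denoising_chain(model, overlap_scene.image, S, sched, seed=11)
        f = sample_noise_fields(S.shape, S, 0.5, 0.25, seed=11)
        for w in sched.w:
            f = denoise_step(model, overlap_scene.image, S, f, float(w))
        np.testing.assert_array_equal(chain.A, f.A)
        np.testing.assert_array_equal(chain.B, f.B)

    def test_fields_stay_in_range_through_many_steps(self, overlap_scene):
        S = overlap_scene.semantic
        sched = make_schedule(20)
        model = ConstantSplitModel(0.9, 0.1)
        f = run_denoising_chain(model, overlap_scene.image, S, sched, seed=2)
        for arr in (f.A, f.B):
            assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestTrainingSamples:
    def test_no_label_drop_keeps_s_and_labels(self, overlap_scene, rng):
        cfg = DiffusionTrainConfig(schedule=make_schedule(4), p_label_drop=0.0)
        smp = make_training_sample(overlap_scene, overlap_scene.semantic, cfg, rng)
        assert len(smp.labels) == len(overlap_scene.labels)
        np.testing.assert_array_equal(smp.s_used.pixels, overlap_scene.semantic.pixels)

    def test_forced_w_zero_means_pure_noise_inputs(self, overlap_scene, rng):
        cfg = DiffusionTrainConfig(schedule=make_schedule(4), p_w_zero=1.0)
        smp = make_training_sample(overlap_scene, overlap_scene.semantic, cfg, rng)
        assert smp.w == 0.0
        np.testing.assert_array_equal(smp.inputs[-2], smp.noise.A)
        np.testing.assert_array_equal(smp.inputs[-1], smp.noise.B)

    def test_w_zero_frequency_matches_probability(self, overlap_scene):
        rng = np.random.default_rng(0)
        cfg = DiffusionTrainConfig(schedule=make_schedule(4), p_w_zero=0.3)
        n = 4000
        hits = sum(
            make_training_sample(overlap_scene, overlap_scene.semantic, cfg, rng).w == 0.0
            for _ in range(n)
        )
        assert abs(hits / n - 0.3) < 0.02

    def test_label_drop_zeroes_exclusive_region(self, two_blob_scene):
        cfg = DiffusionTrainConfig(schedule=make_schedule(4), p_label_drop=0.5)
        rng = np.random.default_rng(3)
        saw_drop = False
        for _ in range(50):
            smp = make_training_sample(two_blob_scene, two_blob_scene.semantic, cfg, rng)
            if len(smp.labels) == 1:
                saw_drop = True
                kept = smp.labels[0].pixels
                dropped = two_blob_scene.semantic.binary & ~kept
                assert np.all(smp.s_used.pixels[dropped] == 0)
                assert np.all(smp.s_used.pixels[kept] == 1)
        assert saw_drop

    def test_certain_drop_exhausts_retries(self, overlap_scene, rng):
        cfg = DiffusionTrainConfig(schedule=make_schedule(4), p_label_drop=1.0)
        with pytest.raises(RuntimeError):
            make_training_sample(overlap_scene, overlap_scene.semantic, cfg, rng)


class TestBootstrap:
    def test_constant_model_targets_are_masked_output(self, overlap_scene):
        S = overlap_scene.semantic
        noise = sample_noise_fields(S.shape, S, seed=1)
        t = bootstrap_targets(ConstantSplitModel(0.8, 0.8), overlap_scene.image, S, noise)
        np.testing.assert_allclose(t.MA, 0.8 * S.pixels, rtol=1e-6)
        assert t.assignment is None

    def test_bootstrap_pass_leaves_no_gradient_trace(self, overlap_scene):
        from diffsplit.diffusion import SplitModel
        from diffsplit.nn import UNet

        unet = UNet(BackboneSpec((4, 8), in_channels=4, out_channels=1), seed=0)
        model = SplitModel(unet)
        unet.zero_grad()
        S = overlap_scene.semantic
        noise = sample_noise_fields(S.shape, S, seed=1)
        bootstrap_targets(model, overlap_scene.image, S, noise)
        assert unet.grad_norm() == 0.0
        assert unet._fwd_cache is None  # nothing cached to backprop through


class TestTrainSplitModel:
    def test_zero_steps_returns_initialized_model(self, small_scenes):
        spec = BackboneSpec((4, 8), in_channels=4, out_channels=2)
        cfg = DiffusionTrainConfig(schedule=make_schedule(4), steps=0, batch_size=2)
        model = train_split_model(small_scenes, spec, cfg)
        assert model.loss_trace == []
        x = _stack_inputs(
            small_scenes[0].image,
            small_scenes[0].semantic,
            sample_noise_fields(
                small_scenes[0].semantic.shape, small_scenes[0].semantic, seed=0
            ),
        )
        assert model.forward(x).shape[1] == 2

    def test_same_seed_identical_loss_traces(self, small_scenes):
        spec = BackboneSpec((4, 8), in_channels=4, out_channels=2)
        cfg = DiffusionTrainConfig(schedule=make_schedule(4), steps=5, batch_size=2, seed=3)
        a = train_split_model(small_scenes, spec, cfg)
        b = train_split_model(small_scenes, spec, cfg)
        assert a.loss_trace == b.loss_trace

    def test_wrong_channel_count_rejected(self, small_scenes):
        spec = BackboneSpec((4, 8), in_channels=3, out_channels=2)
        cfg = DiffusionTrainConfig(schedule=make_schedule(4), steps=1)
        with pytest.raises(ConfigError):
            train_split_model(small_scenes, spec, cfg)

    def test_short_training_reduces_loss(self, small_scenes):
        spec = BackboneSpec((6, 12), in_channels=4, out_channels=2)
        cfg = DiffusionTrainConfig(
            schedule=make_schedule(6), steps=120, batch_size=4, seed=0, lr_end=3e-4
        )
        model = train_split_model(small_scenes, spec, cfg)
        first = float(np.mean(model.loss_trace[:10]))
        last = float(np.mean(model.loss_trace[-10:]))
        assert last < first
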