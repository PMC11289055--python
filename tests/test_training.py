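"""Preprocessing, losses, optimizers, and the seeded training loop."""

import numpy as np
import pytest

import vitreg as v
from vitreg.training import LOSSES, OPTIMIZERS, compute_loss, make_optimizer

NANO_KW = dict(image_size=64, patch_size=8, depth=4, embed_dim=64, num_heads=2)


class TestPreprocess:
    def test_output_shape_and_channels(self):
        out = v.preprocess(np.random.default_rng(0).uniform(size=(50, 70)), size=64)
        assert out.shape == (64, 64, 3)
        # replicated grayscale: channels identical
        assert np.array_equal(out[..., 0], out[..., 1])

    def test_standardised_to_zero_mean_unit_variance(self):
        out = v.preprocess(np.random.default_rng(1).uniform(size=(64, 64)), size=64)
        assert abs(out.mean()) < 1e-5
        assert abs(out.std() - 1.0) < 1e-4

    def test_constant_image_maps_to_zeros(self):
        assert np.all(v.preprocess(np.full((64, 64), 0.5), size=64) == 0.0)

    def test_idempotent_on_preprocessed_input(self):
        once = v.preprocess(np.random.default_rng(2).uniform(size=(64, 64)), size=64)
        twice = v.preprocess(once, size=64)
        np.testing.assert_allclose(twice, once, atol=1e-4)

    def test_rejects_bad_channel_count(self):
        with pytest.raises(ValueError):
            v.preprocess(np.zeros((64, 64, 4)), size=64)


class TestLosses:
    def test_l1_examples(self):
        assert v.l1_loss([1.0, 3.0], [2.0, 5.0], reduction="sum") == 3.0
        assert v.l1_loss([1.0, 3.0], [1.0, 3.0]) == 0.0

    def test_sum_equals_mean_times_batch(self):
        rng = np.random.default_rng(0)
        p, t = rng.uniform(0, 8, 17), rng.uniform(0, 8, 17)
        for loss in LOSSES:
            s, _ = compute_loss(p, t, loss, "sum")
            m, _ = compute_loss(p, t, loss, "mean")
            assert s == pytest.approx(m * 17)

    def test_zero_iff_all_residuals_zero(self):
        for loss in LOSSES:
            val, _ = compute_loss([1.0, 2.0], [1.0, 2.0], loss)
            assert val == 0.0
            val, _ = compute_loss([1.0, 2.1], [1.0, 2.0], loss)
            assert val > 0.0

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        p, t = rng.uniform(0, 8, 9), rng.uniform(0, 8, 9)
        eps = 1e-7
        for loss in LOSSES:
            _, grad = compute_loss(p, t, loss, "mean")
            for i in (0, 4):
                dp = p.copy()
                dp[i] += eps
                up, _ = compute_loss(dp, t, loss, "mean")
                dp[i] -= 2 * eps
                dn, _ = compute_loss(dp, t, loss, "mean")
                assert grad[i] == pytest.approx((up - dn) / (2 * eps), rel=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_loss([1.0], [1.0, 2.0])


class TestOptimizers:
    def test_all_options_update_parameters(self):
        """Loss and optimizer options are interchangeable behind one
        interface (the ablation axes)."""
        for name in OPTIMIZERS:
            net = v.ViTNetwork(
                v.ViTConfig(image_size=16, patch_size=8, depth=1, embed_dim=8,
                            num_heads=2, mlp_ratio=2.0, head_hidden=4),
                seed=0,
            )
            cfg = v.TrainConfig(
                batch_size=2, epochs=1, optimizer=name, cutmix_enabled=False
            )
            before = net.params["head/W1"].copy()
            x = np.random.default_rng(0).uniform(size=(4, 16, 16, 3)).astype(np.float32)
            v.train(net, x, np.array([1.0, 2.0, 3.0, 4.0]), cfg)
            assert not np.array_equal(before, net.params["head/W1"])


class TestTrainLoop:
    def test_overfits_a_single_example(self):
        """With augmentation off, one example must reach L1 loss below
        0.01 within 200 steps on the nano architecture."""
        sample = v.generate_dataset(2, seed=42, score_types=("GE",))[0]
        x = v.preprocess(sample.image, size=64)[None]
        y = np.array([sum(sample.scores["GE"])])
        net = v.ViTNetwork(v.NANO, seed=0)
        cfg = v.TrainConfig(batch_size=1, epochs=200, cutmix_enabled=False, seed=0)
        hist = v.train(net, x, y, cfg)
        assert min(h["train_loss"] for h in hist) < 0.01

    def test_identical_seeds_give_identical_traces_and_weights(self):
        samples = v.generate_dataset(16, seed=6, score_types=("GE",))
        x = [s.image for s in samples]
        y = np.array([sum(s.scores["GE"]) for s in samples])
        runs = []
        for _ in range(2):
            reg = v.ViTRegressor(
                **NANO_KW, epochs=3, batch_size=8, cutmix=True, random_state=7
            )
            reg.fit(x, y)
            runs.append(reg)
        t1 = [h["train_loss"] for h in runs[0].loss_trace_]
        t2 = [h["train_loss"] for h in runs[1].loss_trace_]
        assert t1 == t2
        for key in runs[0].network_.params:
            assert np.array_equal(
                runs[0].network_.params[key], runs[1].network_.params[key]
            )

    def test_loss_decreases_over_training(self):
        samples = v.generate_dataset(32, seed=8, score_types=("GE",))
        x = [s.image for s in samples]
        y = np.array([sum(s.scores["GE"]) for s in samples])
        reg = v.ViTRegressor(**NANO_KW, epochs=8, batch_size=8, cutmix=False,
                             random_state=1)
        reg.fit(x, y)
        trace = [h["train_loss"] for h in reg.loss_trace_]
        assert trace[-1] < trace[0]

    def test_per_lung_supervision_requires_cutmix_off(self):
        with pytest.raises(ValueError):
            net = v.ViTNetwork(v.NANO, seed=0)
            v.train(
                net,
                np.zeros((4, 64, 64, 3), dtype=np.float32),
                np.ones((4, 2)),
                v.TrainConfig(batch_size=2, epochs=1, cutmix_enabled=True),
            )

    def test_validation_mae_logged(self):
        samples = v.generate_dataset(8, seed=9, score_types=("GE",))
        x = np.stack([v.preprocess(s.image, size=64) for s in samples])
        y = np.array([sum(s.scores["GE"]) for s in samples])
        net = v.ViTNetwork(v.NANO, seed=0)
        hist = v.train(
            net, x[:6], y[:6],
            v.TrainConfig(batch_size=2, epochs=2, cutmix_enabled=False),
            val_images=x[6:], val_targets=y[6:],
        )
        assert all("val_mae" in h and h["val_mae"] >= 0 for h in hist)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            v.TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            v.TrainConfig(batch_size=1, cutmix_enabled=True)
        with pytest.raises(ValueError):
            v.TrainConfig(loss="hinge")


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        reg = v.ViTRegressor(**NANO_KW, epochs=2)
        params = reg.get_params()
        assert params["embed_dim"] == 64 and params["epochs"] == 2
        reg.set_params(epochs=5)
        assert reg.train_config().epochs == 5

    def test_clone_compatible(self):
        from sklearn.base import clone

        reg = clone(v.ViTRegressor(**NANO_KW, epochs=2, random_state=3))
        assert reg.random_state == 3

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            v.ViTRegressor(**NANO_KW).predict([np.zeros((64, 64))])
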