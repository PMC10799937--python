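import numpy as np
import pytest

from snagmap.energy_encoding import (check_nesting, energy_to_ordinal,
                                     instances_to_energy)
from snagmap.geodata_io import RunConfig
from snagmap.segmentation_model import (LossConfig, _Adam, augment,
                                        build_network, focal_tversky_grad,
                                        focal_tversky_loss, load_checkpoint,
                                        predict, save_checkpoint, train)
from snagmap.synthetic_scenes import SceneParams, generate_scene


class TestNetwork:
    def test_output_shape_and_range(self):
        net = build_network(4, K=5, width_preset="small", seed=0)
        x = np.random.default_rng(0).uniform(size=(1, 4, 64, 64)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (1, 5, 64, 64)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_zero_input_stays_finite(self):
        net = build_network(4, K=5, seed=0)
        assert np.isfinite(net.forward(np.zeros((1, 4, 32, 32), np.float32))).all()

    def test_batch_order_invariance_in_eval(self):
        net = build_network(4, K=3, seed=1)
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(3, 4, 32, 32)).astype(np.float32)
        fwd = net.forward(x)
        perm = net.forward(x[[2, 0, 1]])
        np.testing.assert_allclose(perm[[1, 2, 0]], fwd, rtol=1e-5, atol=1e-6)

    def test_odd_sizes_padded_internally(self):
        net = build_network(4, K=2, seed=0)
        p = net.forward(np.zeros((1, 4, 30, 37), np.float32))
        assert p.shape == (1, 2, 30, 37)

    def test_gradients_match_finite_differences(self):
        """The hand-derived backward pass agrees with numerical derivatives."""
        net = build_network(4, K=2, width_preset="small", seed=3)
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(2, 4, 8, 8)).astype(np.float32)
        target = (rng.uniform(size=(2, 2, 8, 8)) > 0.7).astype(np.float32)
        cfg = LossConfig()

        def loss_of():
            p = net.forward_train(x)
            return focal_tversky_grad(p.transpose(1, 0, 2, 3),
                                      target.transpose(1, 0, 2, 3), cfg)

        net.zero_grad()
        _, d = loss_of()
        net.backward(d.transpose(1, 0, 2, 3))
        checked = 0
        for p_arr, g_arr in net.parameters()[:2] + net.parameters()[-2:]:
            flat_p = p_arr.reshape(-1)
            flat_g = g_arr.reshape(-1)
            for idx in [0, flat_p.size // 2]:
                eps = 1e-2
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                lp, _ = loss_of()
                flat_p[idx] = orig - eps
                lm, _ = loss_of()
                flat_p[idx] = orig
                num = (lp - lm) / (2 * eps)
                if abs(num) > 1e-5:
                    assert flat_g[idx] == pytest.approx(num, rel=0.15, abs=2e-4)
                    checked += 1
        assert checked >= 2


class TestFocalTverskyLoss:
    def test_perfect_prediction_is_zero(self):
        t = (np.random.default_rng(0).uniform(size=(3, 16, 16)) > 0.5).astype(float)
        assert focal_tversky_loss(t, t) == pytest.approx(0.0, abs=1e-9)

    def test_reduces_to_soft_dice(self):
        rng = np.random.default_rng(1)
        pred = rng.uniform(size=(4, 20, 20))
        target = (rng.uniform(size=(4, 20, 20)) > 0.6).astype(float)
        loss = focal_tversky_loss(pred, target, LossConfig(0.5, 0.5, 1.0), smooth=1.0)
        # independent soft-Dice: 1 - (2 TP + 2s) / (sum p + sum t + 2s)
        dice = []
        for j in range(4):
            tp = (pred[j] * target[j]).sum()
            dice.append(1 - (2 * tp + 2) / (pred[j].sum() + target[j].sum() + 2))
        assert loss == pytest.approx(np.mean(dice), abs=1e-6)

    def test_complement_prediction_saturates(self):
        t = (np.random.default_rng(2).uniform(size=(2, 32, 32)) > 0.5).astype(float)
        loss = focal_tversky_loss(1.0 - t, t, LossConfig(0.4, 0.6, 2.0))
        assert loss == pytest.approx(1.0, abs=0.02)

    def test_empty_target_and_prediction_score_zero(self):
        z = np.zeros((2, 8, 8))
        assert focal_tversky_loss(z, z) == pytest.approx(0.0)

    def test_loss_non_negative(self):
        rng = np.random.default_rng(3)
        loss = focal_tversky_loss(rng.uniform(size=(3, 8, 8)),
                                  (rng.uniform(size=(3, 8, 8)) > 0.5).astype(float))
        assert loss >= 0.0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(0.2, 0.8, size=(2, 6, 6))
        target = (rng.uniform(size=(2, 6, 6)) > 0.5).astype(float)
        cfg = LossConfig()
        _, grad = focal_tversky_grad(pred, target, cfg)
        eps = 1e-6
        for idx in [(0, 1, 2), (1, 4, 4)]:
            p2 = pred.copy()
            p2[idx] += eps
            num = (focal_tversky_loss(p2, target, cfg)
                   - focal_tversky_loss(pred, target, cfg)) / eps
            assert grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-9)


class TestAugment:
    def _patch(self, seed=0):
        b = generate_scene(SceneParams(), seed=seed)
        return b.image.pixels.astype(np.float32) / 255.0, b.truth_instances

    def test_identity_when_probabilities_zero(self):
        img, lab = self._patch()
        out_img, out_lab = augment(img, lab, np.random.default_rng(0),
                                   geometric_p=0.0, spectral_p=0.0)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_lab, lab)

    def test_spectral_only_never_touches_target(self):
        img, lab = self._patch(1)
        _, out_lab = augment(img, lab, np.random.default_rng(1),
                             geometric_p=0.0, spectral_p=1.0)
        np.testing.assert_array_equal(out_lab, lab)

    def test_right_angle_rotation_preserves_count(self):
        img, lab = self._patch(2)
        n_before = np.unique(lab[lab > 0]).size
        # pure 90-degree rotation: no resampling loss of instances
        rot_lab = np.rot90(lab)
        assert np.unique(rot_lab[rot_lab > 0]).size == n_before

    def test_warped_target_still_encodes_nested_energy(self):
        img, lab = self._patch(3)
        _, out_lab = augment(img, lab, np.random.default_rng(7),
                             geometric_p=1.0, spectral_p=0.0, max_shear=0.2)
        e = instances_to_energy(out_lab, K=5)
        assert check_nesting(e)


@pytest.fixture(scope="module")
def overfit_state():
    """Overfit run: the same patch in every split."""
    params = SceneParams(extent_m=38.4, n_crowns=4)
    bundle = generate_scene(params, seed=11)
    cfg = RunConfig(epochs=100, seed=0, batch_size=4, patch_size=64,
                    learning_rate=3e-3, augment_geometric=0.0,
                    augment_spectral=0.0, min_pixels=4)
    return train([bundle] * 5, cfg), cfg, bundle


class TestTraining:
    def test_loss_decreases_on_overfit_run(self, overfit_state):
        state, _, _ = overfit_state
        h = state.history
        assert h.train_loss.iloc[-1] < h.train_loss.iloc[0]

    def test_overfit_run_reaches_zero_count_mae(self, overfit_state):
        state, _, _ = overfit_state
        assert state.best_val_count_mae == 0.0

    def test_selection_returns_argmin_of_history(self, overfit_state):
        state, _, _ = overfit_state
        h = state.history
        assert state.best_val_count_mae == h.val_count_mae.min()
        assert h.loc[h.epoch == state.best_epoch, "val_count_mae"].iloc[0] \
            == h.val_count_mae.min()

    def test_fixed_seed_reproduces_history(self):
        params = SceneParams(extent_m=38.4, n_crowns=3)
        bundles = [generate_scene(params, seed=s) for s in range(4)]
        cfg = RunConfig(epochs=2, seed=5, batch_size=2)
        h1 = train(bundles, cfg).history
        h2 = train(bundles, cfg).history
        assert h1.equals(h2)

    def test_predict_band_mismatch_raises(self, overfit_state):
        state, cfg, bundle = overfit_state
        from snagmap.geodata_io import RasterTile

        bad = RasterTile(bundle.image.pixels[:3], bundle.image.transform,
                         bundle.image.crs)
        with pytest.raises(ValueError):
            predict(state.network, bad, cfg)

    def test_predict_deterministic_and_stitching_consistent(self, overfit_state):
        state, cfg, bundle = overfit_state
        import dataclasses

        e1 = predict(state.network, bundle.image, cfg)
        e2 = predict(state.network, bundle.image, cfg)
        np.testing.assert_array_equal(e1.levels, e2.levels)
        # stitched prediction stays close to whole-image prediction even for
        # this barely-trained model (the trained-model check lives in the
        # end-to-end suite at a tighter threshold)
        big = generate_scene(SceneParams(extent_m=153.6, n_crowns=30), seed=99)
        e_whole = predict(state.network, big.image,
                          dataclasses.replace(cfg, patch_size=512))
        tiled_cfg = dataclasses.replace(cfg, patch_size=128, patch_overlap=32)
        e3 = predict(state.network, big.image, tiled_cfg)
        agree = (e3.levels == e_whole.levels).mean()
        assert agree >= 0.95

    def test_checkpoint_round_trip(self, overfit_state, tmp_path):
        state, cfg, bundle = overfit_state
        save_checkpoint(tmp_path / "ck.npz", state.network, cfg)
        net = load_checkpoint(tmp_path / "ck.npz")
        x = bundle.image.pixels.astype(np.float32)[None] / 255.0
        np.testing.assert_allclose(net.forward(x), state.network.forward(x),
                                   rtol=1e-6)


class TestAdam:
    def test_descends_a_quadratic(self):
        p = np.array([5.0, -3.0], dtype=np.float32)
        g = np.zeros_like(p)
        opt = _Adam([(p, g)], lr=0.1)
        for _ in range(300):
            g[...] = 2 * p
            opt.step()
        assert np.abs(p).max() < 0.1
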