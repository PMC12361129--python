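import numpy as np
import pytest

from axonfield.io import Volume
from axonfield.labels import make_distance_field, resample_skeleton
from axonfield.segnet import (
    TrainConfig,
    enhance,
    extract_foreground,
    predict,
    region_weighted_l1,
    skeletonize,
    train,
)
from axonfield.unet import NetConfig, UNet3D, full_profile, toy_profile

from conftest import make_chain


def brute_loss(y_p, y_g, x, t1=3 / 255, t2=103 / 255):
    """Voxel-by-voxel reimplementation of the four-term loss."""
    terms = [0.0, 0.0, 0.0, 0.0]
    counts = [y_p.size, 0, 0, 0]
    for idx in np.ndindex(y_p.shape):
        d = abs(float(y_p[idx]) - float(y_g[idx]))
        terms[0] += d
        if y_g[idx] > t1:
            terms[1] += d
            counts[1] += 1
        if y_g[idx] > t2:
            terms[2] += d
            counts[2] += 1
        if x[idx] > t2:
            terms[3] += d
            counts[3] += 1
    return sum(t / c for t, c in zip(terms, counts) if c)


class TestArchitecture:
    @pytest.mark.parametrize(
        "cfg,shape",
        [
            (toy_profile(), (20, 24, 28)),  # toy profile, non-divisible shape
            (NetConfig(levels=3, base_channels=8), (16, 16, 16)),
        ],
    )
    def test_output_shape_equals_input_shape(self, cfg, shape, rng):
        model = UNet3D(cfg, seed=0)
        x = rng.random(shape, dtype=np.float32)
        y = model.forward(x)
        assert y.shape == shape
        assert 0.0 <= y.min() and y.max() <= 1.0

    def test_full_scale_profile_shape_contract(self, rng):
        # 6 levels, channels 16 doubling to 512; input divisible by 2^5
        cfg = full_profile()
        assert cfg.channels == [16, 32, 64, 128, 256, 512]
        model = UNet3D(cfg, seed=0)
        x = rng.random((32, 32, 32), dtype=np.float32)
        assert model.forward(x).shape == (32, 32, 32)

    def test_too_small_input_raises_with_guidance(self):
        model = UNet3D(NetConfig(levels=4, base_channels=2), seed=0)
        with pytest.raises(ValueError, match="pad"):
            model.forward(np.zeros((4, 4, 4), dtype=np.float32))

    def test_toy_profile_parameter_count_frozen(self):
        # independent layer-by-layer tally: encoder 1960+10400+41536,
        # upsamplers 1032+4112, decoder 3472+13856, head 9
        assert UNet3D(toy_profile()).n_parameters() == 76377

    def test_same_seed_gives_identical_weights(self):
        a = UNet3D(toy_profile(), seed=5)
        b = UNet3D(toy_profile(), seed=5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_concat_skip_mode_shape_contract(self, rng):
        model = UNet3D(NetConfig(levels=3, base_channels=4, skip_mode="concat"), seed=0)
        x = rng.random((16, 16, 16), dtype=np.float32)
        assert model.forward(x).shape == (16, 16, 16)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        model = UNet3D(NetConfig(levels=2, base_channels=2), seed=3).astype(np.float64)
        x = rng.random((6, 6, 6))
        direction = rng.normal(size=(6, 6, 6))

        def objective():
            return float((model.forward(x, clamp=False) * direction).sum())

        for p in model.params():
            p.zero_grad()
        model.forward(x, clamp=False)
        model.backward(direction)
        for p in model.params():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in rng.integers(0, flat.size, size=min(2, flat.size)):
                old, eps = flat[i], 1e-6
                flat[i] = old + eps
                fp = objective()
                flat[i] = old - eps
                fm = objective()
                flat[i] = old
                num = (fp - fm) / (2 * eps)
                assert num == pytest.approx(gflat[i], rel=1e-4, abs=1e-7)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = UNet3D(toy_profile(), seed=2)
        x = rng.random((16, 16, 16), dtype=np.float32)
        y1 = model.forward(x)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        y2 = UNet3D.load(path).forward(x)
        np.testing.assert_array_equal(y1, y2)


class TestLoss:
    def test_zero_when_prediction_equals_label(self, rng):
        y = rng.random((4, 4, 4))
        assert region_weighted_l1(y, y, rng.random((4, 4, 4))) == 0.0

    def test_hand_computed_example(self):
        y_g = np.full((2, 2, 2), 0.5)
        y_p = np.full((2, 2, 2), 0.3)
        x = np.zeros((2, 2, 2))
        # global, reg1 and reg2 terms each 0.2; reg2* is empty
        assert region_weighted_l1(y_p, y_g, x) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_voxelwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y_p, y_g, x = (rng.random((8, 8, 8)) for _ in range(3))
        assert region_weighted_l1(y_p, y_g, x) == pytest.approx(
            brute_loss(y_p, y_g, x), abs=1e-6
        )

    def test_nonnegative(self, rng):
        for _ in range(10):
            y_p, y_g, x = (rng.random((5, 5, 5)) for _ in range(3))
            assert region_weighted_l1(y_p, y_g, x) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            region_weighted_l1(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))


class TestPredict:
    def test_output_clamped_to_unit_interval(self, rng):
        model = UNet3D(toy_profile(), seed=0)
        out = predict(model, rng.random((16, 16, 16), dtype=np.float32))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_tiled_agrees_with_untiled(self, rng):
        # margin 24 exceeds the toy net's receptive-field radius (~22), so
        # every written voxel sees exactly the data an untiled pass would see
        model = UNet3D(toy_profile(), seed=1)
        vol = rng.random((72, 72, 72), dtype=np.float32)
        untiled = model.forward(vol)
        tiled = predict(model, vol, tile=64, margin=24)
        np.testing.assert_allclose(tiled, untiled, atol=1e-5)


class TestEnhance:
    def _vol(self, raw):
        return Volume(np.asarray(raw, dtype=np.float32) / 255.0, source_dtype_max=255)

    def test_zero_prediction_is_identity(self, rng):
        vol = self._vol(rng.integers(0, 256, size=(8, 8, 8)))
        out = enhance(vol, np.zeros(vol.shape, dtype=np.float32))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_saturating_overlay_clips_at_255(self):
        vol = self._vol(np.full((2, 2, 2), 10))
        out = enhance(vol, np.ones((2, 2, 2)))
        np.testing.assert_allclose(out.raw(), 255.0)

    def test_partial_overlay_arithmetic(self):
        vol = self._vol(np.full((2, 2, 2), 100))
        out = enhance(vol, np.full((2, 2, 2), 0.2))
        np.testing.assert_allclose(out.raw(), 151.0, atol=1e-4)  # 100 + 0.2 * 255

    def test_idempotent_in_saturated_limit(self, rng):
        vol = self._vol(rng.integers(0, 256, size=(6, 6, 6)))
        pred = rng.random((6, 6, 6)).astype(np.float32)
        once = enhance(vol, pred)
        twice = enhance(once, pred)
        assert (twice.data >= once.data - 1e-7).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            enhance(self._vol(np.zeros((4, 4, 4))), np.zeros((2, 2, 2)))


class TestForegroundAndSkeletonize:
    def test_zero_field_has_no_foreground(self):
        assert extract_foreground(np.zeros((5, 5, 5)), 0.5).shape == (0, 3)

    def test_exactly_the_above_threshold_voxels(self, rng):
        pred = rng.random((6, 6, 6))
        pts = extract_foreground(pred, 0.7)
        want = {(x, y, z) for z, y, x in zip(*np.nonzero(pred > 0.7))}
        got = {tuple(int(c) for c in p) for p in pts}
        assert got == want
        assert len(pts) == int((pred > 0.7).sum())  # brute-force count

    def test_collinear_points_give_single_path_tree(self):
        pts = np.array([[float(i), 0.0, 0.0] for i in range(12)])
        trees = skeletonize(pts)
        assert len(trees) == 1
        tree = trees[0]
        assert len(tree) == 12
        degrees = {n.id: 0 for n in tree.nodes}
        for n in tree.nodes:
            if n.parent_id != -1:
                degrees[n.parent_id] += 1
        assert max(degrees.values()) == 1  # unbranched

    def test_single_point(self):
        trees = skeletonize(np.array([[1.0, 2.0, 3.0]]))
        assert len(trees) == 1 and len(trees[0]) == 1

    def test_distant_clusters_split_into_trees(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[50.0, 0, 0], [51.0, 0, 0]])
        trees = skeletonize(np.concatenate([a, b]), edge_cutoff=2.0)
        assert len(trees) == 2

    def test_short_spur_is_pruned(self):
        spine = [[float(i), 0.0, 0.0] for i in range(15)]
        spur = [[7.0, float(j), 0.0] for j in range(1, 3)]
        trees = skeletonize(np.array(spine + spur), prune_length=4.0)
        assert len(trees) == 1
        assert len(trees[0]) == 15  # spur nodes removed, spine intact

    def test_empty_input(self):
        assert skeletonize(np.empty((0, 3))) == []


class TestTrain:
    def _tiny_pair(self, seed=0, shape=(16, 16, 16)):
        rng = np.random.default_rng(seed)
        tree = resample_skeleton(
            make_chain([(2.0, 8.0, 8.0), (float(shape[2] - 3), 8.0, 8.0)])
        )
        label = make_distance_field([tree], shape)
        raw = rng.normal(12, 6, size=shape) + 120 * label
        vol = Volume(np.clip(raw, 0, 255) / 255.0, 255)
        return vol, label

    def test_two_epoch_history_is_finite(self):
        pair = self._tiny_pair()
        _, hist = train([pair], NetConfig(levels=2, base_channels=4),
                        TrainConfig(epochs=2, seed=0))
        assert len(hist["train_loss"]) == 2
        assert all(np.isfinite(v) for v in hist["train_loss"] + hist["val_loss"])

    def test_same_seed_reproduces_first_epoch_loss(self):
        pair = self._tiny_pair()
        cfg = NetConfig(levels=2, base_channels=4)
        _, h1 = train([pair], cfg, TrainConfig(epochs=1, seed=7))
        _, h2 = train([pair], cfg, TrainConfig(epochs=1, seed=7))
        assert h1["train_loss"][0] == h2["train_loss"][0]

    def test_validation_loss_improves_on_small_corpus(self):
        pairs = [self._tiny_pair(seed=s) for s in range(6)]
        _, hist = train(pairs, NetConfig(levels=2, base_channels=4),
                        TrainConfig(epochs=4, seed=0))
        assert hist["val_loss"][-1] < hist["val_loss"][0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], NetConfig(levels=2, base_channels=2), TrainConfig(epochs=1))
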