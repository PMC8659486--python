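import numpy as np
import pytest

from renalseg.localizer import (
    CLASS_LEFT,
    CLASS_RIGHT,
    RbUNetConfig,
    boxes_from_coarse_labels,
    build_rb_unet,
    downsample_labels,
    load_localizer,
    predict_boxes,
    save_checkpoint,
    split_left_right,
    train_localizer,
    weighted_cross_entropy,
)
from renalseg.nn import Tensor
from renalseg.nn import functional as F
from renalseg.nn.tensor import no_grad
from renalseg.preprocess import preprocess_series
from renalseg.training import OptimizerConfig
from renalseg.volumes import BoundingBox3D

SMALL_NET = RbUNetConfig(base_filters=4, dropout_rate=0.0)


class TestArchitecture:
    def test_forward_shape_contract(self):
        model = build_rb_unet(SMALL_NET).eval()
        x = Tensor(np.random.default_rng(0).normal(size=(1, 5, 32, 32, 32)).astype(np.float32))
        with no_grad():
            out = model(x)
        assert out.data.shape == (1, 3, 32, 32, 32)

    def test_rejects_indivisible_input(self):
        model = build_rb_unet(SMALL_NET).eval()
        with pytest.raises(ValueError, match="divide"):
            with no_grad():
                model(Tensor(np.zeros((1, 5, 24, 24, 24), np.float32)))

    def test_backprop_reaches_first_layer(self):
        model = build_rb_unet(SMALL_NET).train()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 5, 16, 16, 16)).astype(np.float32))
        probs = F.softmax_channel(model(x))
        truth = np.random.default_rng(2).integers(0, 3, size=(1, 16, 16, 16))
        loss = weighted_cross_entropy(probs, truth)
        loss.backward()
        first = model.enc[0].conv1.weight
        assert first.grad is not None and np.abs(first.grad).max() > 0

    def test_residual_shortcuts_are_live(self):
        with_res = build_rb_unet(SMALL_NET, residual=True).eval()
        without = build_rb_unet(SMALL_NET, residual=False).eval()
        # transplant the shared weights so only the shortcut wiring differs
        state = dict(with_res.state_dict())
        sub = {k: v for k, v in state.items() if k in dict(without.state_dict())}
        missing = {k: v for k, v in without.state_dict().items() if k not in sub}
        without.load_state_dict({**missing, **sub})
        x = Tensor(np.random.default_rng(3).normal(size=(1, 5, 16, 16, 16)).astype(np.float32))
        with no_grad():
            a = with_res(x)
            b = without(x)
        assert not np.allclose(a.data, b.data)


class TestWeightedCrossEntropy:
    def test_perfect_confident_prediction_limit(self):
        truth = np.array([[[[0, 1], [2, 0]], [[1, 2], [0, 1]]]])
        losses = []
        for margin in (1e-2, 1e-4, 1e-6):
            probs = np.full((1, 3, 2, 2, 2), margin / 2, np.float32)
            for c in range(3):
                probs[0, c][truth[0] == c] = 1 - margin
            probs /= probs.sum(axis=1, keepdims=True)
            losses.append(float(weighted_cross_entropy(probs, truth).data))
        assert losses[0] > losses[1] > losses[2]
        assert losses[-1] < 1e-4

    def test_uniform_half_probability_oracle(self):
        # every (voxel, channel) term is log 2 at p=0.5 with unit weights
        probs = np.full((1, 3, 2, 2, 2), 0.5, np.float32)
        truth = np.random.default_rng(0).integers(0, 3, size=(1, 2, 2, 2))
        loss = float(weighted_cross_entropy(probs, truth, np.ones(3)).data)
        assert loss == pytest.approx(3 * np.log(2), rel=1e-6)

    def test_hand_summed_oracle_2x2x2(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(1, 3, 2, 2, 2))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        truth = rng.integers(0, 3, size=(1, 2, 2, 2))
        weights = np.array([1.0, 2.5, 4.0])
        expected = 0.0
        for z in range(2):
            for y in range(2):
                for x in range(2):
                    w = weights[truth[0, z, y, x]]
                    for c in range(3):
                        p = probs[0, c, z, y, x]
                        yhat = 1.0 if truth[0, z, y, x] == c else 0.0
                        expected += -w * (yhat * np.log(p) + (1 - yhat) * np.log(1 - p))
        expected /= 8
        got = float(weighted_cross_entropy(probs.astype(np.float32), truth, weights).data)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_minority_weight_linearity(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(size=(1, 2, 2, 2, 2))
        probs = (np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)).astype(np.float32)
        truth = np.array([[[[0, 1], [0, 0]], [[0, 0], [0, 0]]]])  # one minority voxel

        def loss_with(w1):
            return float(weighted_cross_entropy(probs, truth, np.array([1.0, w1])).data)

        base = loss_with(0.0)  # background-only contribution
        assert loss_with(4.0) - base == pytest.approx(2 * (loss_with(2.0) - base), rel=1e-5)

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(6)
        logits = rng.normal(size=(2, 3, 4, 4, 4))
        probs = (np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)).astype(np.float32)
        truth = rng.integers(0, 3, size=(2, 4, 4, 4))
        assert float(weighted_cross_entropy(probs, truth).data) >= 0.0


class TestLabelsAndBoxes:
    def test_split_left_right_by_midline(self, clean_phantom):
        labels = split_left_right(clean_phantom.whole_mask)
        right = clean_phantom.right_mask.data > 0
        left = clean_phantom.left_mask.data > 0
        assert (labels[right] == CLASS_RIGHT).all()
        assert (labels[left] == CLASS_LEFT).all()
        assert (labels[~(right | left)] == 0).all()

    def test_single_coarse_voxel_maps_to_scale_factor_box(self):
        labels64 = np.zeros((64, 64, 64), np.uint8)
        labels64[10, 20, 30] = CLASS_LEFT
        left, right = boxes_from_coarse_labels(labels64, (128, 128, 128))
        assert left.present and not right.present
        assert left.extent == (2, 2, 2)  # one coarse voxel = one 2x2x2 cell
        assert (left.zmin, left.ymin, left.xmin) == (20, 40, 60)

    def test_empty_class_gives_absent_box(self):
        left, right = boxes_from_coarse_labels(np.zeros((64, 64, 64), np.uint8), (64, 64, 64))
        assert not left.present and not right.present
        assert left.extent == (1, 1, 1)

    def test_oracle_model_boxes_contain_kidneys(self, clean_phantom):
        truth = clean_phantom

        class OracleModel:
            def predict(self, x):
                labels = downsample_labels(split_left_right(truth.whole_mask), x.shape[1:])

                class P:
                    argmax_labels = labels

                return P()

        left, right = predict_boxes(OracleModel(), truth.series, target=(32, 32, 32))
        for box, mask in ((left, truth.left_mask), (right, truth.right_mask)):
            assert box.present
            fg = np.argwhere(mask.data)
            assert (fg[:, 0] >= box.zmin).all() and (fg[:, 0] <= box.zmax).all()
            assert (fg[:, 1] >= box.ymin).all() and (fg[:, 1] <= box.ymax).all()
            assert (fg[:, 2] >= box.xmin).all() and (fg[:, 2] <= box.xmax).all()

    def test_missing_kidney_absent_box(self, missing_kidney_phantom):
        truth = missing_kidney_phantom

        class OracleModel:
            def predict(self, x):
                labels = downsample_labels(split_left_right(truth.whole_mask), x.shape[1:])

                class P:
                    argmax_labels = labels

                return P()

        left, right = predict_boxes(OracleModel(), truth.series, target=(32, 32, 32))
        assert right.present and not left.present
        assert left.extent == (1, 1, 1)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_dataset(self, clean_phantom):
        target = (16, 16, 16)
        red = preprocess_series(clean_phantom.series, target=target)
        labels = downsample_labels(split_left_right(clean_phantom.whole_mask), target)
        return [(red.data, labels)] * 2

    def test_zero_lr_flat_history(self, tiny_dataset):
        _, hist = train_localizer(
            tiny_dataset, SMALL_NET, OptimizerConfig(lr=0.0, epochs=3, batch_size=2, seed=0)
        )
        assert hist[0] == pytest.approx(hist[1]) == pytest.approx(hist[2])

    def test_same_seed_identical_history(self, tiny_dataset):
        cfg = OptimizerConfig(lr=1e-3, epochs=2, batch_size=2, seed=3)
        _, h1 = train_localizer(tiny_dataset, SMALL_NET, cfg)
        _, h2 = train_localizer(tiny_dataset, SMALL_NET, cfg)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_localizer([], SMALL_NET, OptimizerConfig(epochs=1))

    def test_checkpoint_roundtrip(self, tiny_dataset, tmp_path):
        model, _ = train_localizer(
            tiny_dataset, SMALL_NET, OptimizerConfig(lr=1e-3, epochs=1, batch_size=2, seed=0)
        )
        path = tmp_path / "loc.npz"
        save_checkpoint(model, path)
        loaded = load_localizer(path, SMALL_NET)
        x = np.random.default_rng(0).normal(size=(5, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(model.predict(x).argmax_labels, loaded.predict(x).argmax_labels)
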