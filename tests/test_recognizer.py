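import numpy as np
import pytest

from mindreach import recognizer
from mindreach.recognizer import (
    CLASSES,
    CnnSpec,
    CropDataset,
    augment,
    build,
    make_crops,
    mirror,
    predict,
    rescale,
    train,
)
from mindreach.recognizer.nn import Conv2D, Dense, cross_entropy_grad


class TestBuild:
    def test_first_conv_parameter_count(self):
        model = build(CnnSpec(input_shape=(3, 32, 32)), seed=0)
        counts = dict(model.parameter_counts())
        # independent per-layer arithmetic: 32 kernels of 3x3x3 plus biases
        assert counts["Conv2D(3->32, 3x3, same)"] == 32 * (3 * 3 * 3) + 32 == 896

    def test_architecture_audit(self):
        model = build(CnnSpec(input_shape=(3, 32, 32)), seed=0)
        conv_stages = [s for s in model.stages() if s.startswith("Conv2D")]
        dense_stages = [s for s in model.stages() if s.startswith("Dense")]
        assert conv_stages == [
            "Conv2D(3->32, 3x3, same)",
            "Conv2D(32->64, 3x3, same)",
            "Conv2D(64->128, 3x3, same)",
            "Conv2D(128->256, 3x3, same)",
        ]
        assert dense_stages == [
            "Dense(1024->256)", "Dense(256->128)", "Dense(128->64)", "Dense(64->4)",
        ]
        assert model.stages().count("MaxPool2x2") == 4
        assert model.stages().count("Dropout(p=0.5)") == 1
        # dropout sits between the third and fourth fully connected layers
        idx = model.stages().index("Dropout(p=0.5)")
        assert model.stages()[idx + 1] == "Dense(64->4)"

    def test_reference_scale_pooled_sides(self):
        model = build(CnnSpec(), seed=0)
        x = np.zeros((1, 3, 200, 200))
        sides = []
        for layer in model.layers:
            x = layer.forward(x)
            if type(layer).__name__ == "MaxPool2x2":
                sides.append(x.shape[2])
        assert sides == [100, 50, 25, 12]

    def test_output_width_four(self):
        model = build(CnnSpec(input_shape=(3, 16, 16)), seed=0)
        out = model.forward(np.zeros((2, 3, 16, 16)))
        assert out.shape == (2, 4)

    def test_too_small_input_names_failing_pool(self):
        with pytest.raises(ValueError, match="pool stage 4"):
            build(CnnSpec(input_shape=(3, 8, 8)), seed=0)


class TestGradients:
    def test_finite_difference_check(self):
        """Analytic backprop vs central finite differences on a tiny net."""
        rng = np.random.default_rng(0)
        conv = Conv2D(2, 3, 3, rng)
        dense = Dense(3 * 4 * 4, 4, rng)
        x = rng.normal(size=(2, 2, 4, 4))
        y = np.array([1, 3])

        def loss_value():
            h = conv.forward(x)
            h = np.maximum(h, 0.0)
            logits = dense.forward(h.reshape(2, -1))
            loss, _ = cross_entropy_grad(logits, y)
            return loss

        h = conv.forward(x)
        relu_mask = h > 0
        logits = dense.forward((h * relu_mask).reshape(2, -1))
        _, dlogits = cross_entropy_grad(logits, y)
        dh = dense.backward(dlogits).reshape(h.shape) * relu_mask
        conv.backward(dh)

        eps = 1e-6
        for layer in (conv, dense):
            for key in layer.params:
                flat = layer.params[key].ravel()
                n_probe = min(5, flat.size)
                for idx in rng.choice(flat.size, size=n_probe, replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up = loss_value()
                    flat[idx] = orig - eps
                    down = loss_value()
                    flat[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    assert layer.grads[key].ravel()[idx] == pytest.approx(
                        numeric, rel=1e-4, abs=1e-7
                    )


class TestAugment:
    def test_mirror_twice_identity(self):
        img = np.random.default_rng(1).random((8, 8, 3))
        assert np.array_equal(mirror(mirror(img)), img)

    def test_count_contract_3n(self):
        ds = make_crops(5, size=16, seed=0)
        out = augment(ds)
        assert len(out) == 3 * len(ds)
        assert out.labels[: len(ds)] == ds.labels
        # each copy keeps its source label
        for i in range(len(ds)):
            assert out.labels[len(ds) + 2 * i] == ds.labels[i]
            assert out.labels[len(ds) + 2 * i + 1] == ds.labels[i]

    def test_rescale_factor_one_identical(self):
        img = np.random.default_rng(2).random((12, 12, 3))
        assert np.array_equal(rescale(img, 1.0), img)

    def test_rescale_preserves_shape(self):
        img = np.random.default_rng(3).random((16, 16, 3))
        for factor in (0.75, 1.25):
            assert rescale(img, factor).shape == img.shape

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            augment(CropDataset([], []))


class TestDataset:
    def test_crops_shape_and_labels(self):
        ds = make_crops(3, size=16, seed=4)
        assert len(ds) == 12
        assert sorted(set(ds.labels)) == [0, 1, 2, 3]
        for img in ds.images:
            assert img.shape == (16, 16, 3)
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_split_preserves_class_presence(self):
        ds = make_crops(4, size=16, seed=5).train_val_split(0.7, seed=1)
        tr_labels = {l for l, s in zip(ds.labels, ds.split) if s == "train"}
        assert tr_labels == {0, 1, 2, 3}

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            CropDataset([np.zeros((4, 4, 3))], [7])


@pytest.fixture(scope="module")
def overfit():
    ds = make_crops(4, size=16, seed=3)          # 16 crops, train-only
    model = build(CnnSpec(input_shape=(3, 16, 16)), seed=1)
    trace = train(model, ds, epochs=40, seed=1)
    return model, ds, trace


class TestTrainPredict:

    def test_small_overfit_run(self, overfit):
        _, _, trace = overfit
        assert trace["train_accuracy"][-1] >= 0.9

    def test_training_crop_predicted_correctly(self, overfit):
        model, ds, trace = overfit
        hits = sum(
            int(np.argmax(predict(model, img)) == lbl)
            for img, lbl in zip(ds.images, ds.labels)
        )
        assert hits / len(ds) == pytest.approx(trace["train_accuracy"][-1])

    def test_softmax_sums_to_one(self, overfit):
        model, ds, _ = overfit
        for img in ds.images[:4]:
            assert predict(model, img).sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(predict(model, img) >= 0)

    def test_inference_deterministic_dropout_off(self, overfit):
        model, ds, _ = overfit
        a = predict(model, ds.images[0])
        b = predict(model, ds.images[0])
        assert np.array_equal(a, b)

    def test_zero_epochs_chance_level(self):
        ds = make_crops(10, size=16, seed=6)
        model = build(CnnSpec(input_shape=(3, 16, 16)), seed=2)
        trace = train(model, ds, epochs=0, seed=2)
        assert trace["train_accuracy"] == []
        hits = np.mean([
            int(np.argmax(predict(model, img)) == lbl)
            for img, lbl in zip(ds.images, ds.labels)
        ])
        assert abs(hits - 0.25) <= 0.10

    def test_shuffled_labels_give_chance_validation(self):
        ds = make_crops(8, size=16, seed=7).train_val_split(0.7, seed=0)
        rng = np.random.default_rng(0)
        shuffled = CropDataset(
            list(ds.images), list(rng.permutation(ds.labels)), list(ds.split)
        )
        try:
            model = build(CnnSpec(input_shape=(3, 16, 16)), seed=3)
            trace = train(model, shuffled, epochs=5, seed=3)
        except ValueError:
            pytest.skip("shuffle removed a class from the training split")
        assert trace["val_accuracy"][-1] <= 0.6

    def test_missing_class_raises(self):
        ds = make_crops(3, size=16, seed=8)
        only_two = CropDataset(
            [img for img, l in zip(ds.images, ds.labels) if l < 2],
            [l for l in ds.labels if l < 2],
        )
        model = build(CnnSpec(input_shape=(3, 16, 16)), seed=0)
        with pytest.raises(ValueError, match="missing classes"):
            train(model, only_two, epochs=1, seed=0)

    def test_wrong_input_shape_raises(self, overfit):
        model, _, _ = overfit
        with pytest.raises(ValueError, match="channels"):
            predict(model, np.zeros((16, 16, 1)))
        with pytest.raises(ValueError, match="resize"):
            predict(model, np.zeros((20, 20, 3)))

    def test_label_permutation_equivariance(self):
        """Permuting class indices (and the output layer's init to match)
        permutes the predicted distribution exactly."""
        perm = np.array([2, 0, 3, 1])
        ds = make_crops(3, size=16, seed=9)
        ds_perm = CropDataset(
            list(ds.images), [int(perm[l]) for l in ds.labels], list(ds.split)
        )
        model_a = build(CnnSpec(input_shape=(3, 16, 16)), seed=4)
        model_b = build(CnnSpec(input_shape=(3, 16, 16)), seed=4)
        # output slot perm[k] of model B plays the role slot k plays in A
        final_a, final_b = model_a.layers[-1], model_b.layers[-1]
        final_b.params["W"][:, perm] = final_a.params["W"].copy()
        final_b.params["b"][perm] = final_a.params["b"].copy()
        train(model_a, ds, epochs=3, seed=5)
        train(model_b, ds_perm, epochs=3, seed=5)
        for img in ds.images[:4]:
            pa = predict(model_a, img)
            pb = predict(model_b, img)
            assert np.allclose(pb[perm], pa, atol=1e-10)
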