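"""CNN construction, split protocols, training sanity, metrics."""

import numpy as np
import pytest

from imucanvas.classifier import (
    CNNConfig,
    ConfusionCounts,
    build_model,
    confusion_from_predictions,
    evaluate,
    metrics_from_confusion,
    stratified_fractions,
    stratified_kfold,
    train,
)


class TestMetrics:
    def test_direct_formula_application(self):
        conf = ConfusionCounts(counts={"pos": (50, 10, 10, 30)}, n_total=100)
        m = metrics_from_confusion(conf).per_class["pos"]
        assert m["precision"] == pytest.approx(50 / 60)
        assert m["recall"] == pytest.approx(50 / 60)
        assert m["accuracy"] == pytest.approx(0.80)
        assert m["f1"] == pytest.approx(50 / 60)

    def test_perfect_predictions(self):
        y = ["a", "b", "a", "b"]
        conf = confusion_from_predictions(y, y)
        rep = metrics_from_confusion(conf)
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for m in rep.per_class.values() for v in m.values())

    def test_zero_denominators_give_zero(self):
        conf = confusion_from_predictions(["a", "a", "b"], ["b", "b", "b"])
        m = metrics_from_confusion(conf).per_class["a"]
        assert m["precision"] == 0.0 and m["recall"] == 0.0 and m["f1"] == 0.0

    def test_matches_sklearn_on_random_predictions(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        y_true = rng.integers(0, 4, size=200).astype(str)
        y_pred = rng.integers(0, 4, size=200).astype(str)
        rep = metrics_from_confusion(confusion_from_predictions(y_true, y_pred))
        classes = sorted(set(y_true) | set(y_pred))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0
        )
        for i, cls in enumerate(classes):
            assert rep.per_class[cls]["precision"] == pytest.approx(p[i])
            assert rep.per_class[cls]["recall"] == pytest.approx(r[i])
            assert rep.per_class[cls]["f1"] == pytest.approx(f[i])
        assert rep.overall_accuracy == pytest.approx(float((y_true == y_pred).mean()))

    def test_counts_sum_to_total_per_class(self, rng):
        y_true = rng.integers(0, 3, size=50).astype(str)
        y_pred = rng.integers(0, 3, size=50).astype(str)
        conf = confusion_from_predictions(y_true, y_pred)
        for tp, fp, fn, tn in conf.counts.values():
            assert tp + fp + fn + tn == 50


class TestSplits:
    def test_kfold_partitions_disjoint_and_exhaustive(self):
        labels = np.array(["a"] * 50 + ["b"] * 50)
        folds = stratified_kfold(labels, 10, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(100))
        for tr, te in folds:
            assert len(te) == 10
            assert set(tr) & set(te) == set()
            # stratification within +-1 item per class
            assert abs(int((labels[te] == "a").sum()) - 5) <= 1

    def test_fractions_are_stratified(self):
        labels = np.array(["a"] * 40 + ["b"] * 60)
        tr, te = stratified_fractions(labels, (0.8, 0.2), seed=0)
        assert len(tr) + len(te) == 100
        assert set(tr) & set(te) == set()
        assert abs(int((labels[te] == "a").sum()) - 8) <= 1

    def test_three_way_fractions(self):
        labels = np.array(["a", "b"] * 50)
        tr, va, te = stratified_fractions(labels, (0.8, 0.1, 0.1), seed=0)
        assert len(tr) + len(va) + len(te) == 100
        assert not (set(tr) & set(va) | set(tr) & set(te) | set(va) & set(te))

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError):
            stratified_fractions(["a", "b"], (0.5, 0.4), seed=0)

    def test_kfold_is_seeded(self):
        labels = ["a", "b"] * 20
        a = stratified_kfold(labels, 4, seed=7)
        b = stratified_kfold(labels, 4, seed=7)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tea, teb)


def toy_images(rng, n_per_class=20, size=12):
    """Linearly separable rasters: class 0 bright left half, class 1 right."""
    images, labels = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            img = rng.integers(0, 40, size=(size, size)).astype(np.uint8)
            half = np.s_[:, :size // 2] if cls == 0 else np.s_[:, size // 2:]
            img[half] = rng.integers(200, 255, size=(size, size // 2))
            images.append(img)
            labels.append(f"c{cls}")
    return np.stack(images), np.array(labels)


class TestModel:
    def test_parameter_count_matches_closed_form(self):
        cfg = CNNConfig(conv_filters=(8, 8), dense_units=16)
        model = build_model(cfg, (12, 12, 1), 3)
        # 12 -conv3-> 10 -pool-> 5 -conv3-> 3 -pool-> 1
        expected = (
            (3 * 3 * 1 * 8 + 8)
            + (3 * 3 * 8 * 8 + 8)
            + (1 * 1 * 8 * 16 + 16)
            + (16 * 3 + 3)
        )
        assert model.param_count == expected

    def test_layer_sequence(self):
        from imucanvas import nn

        model = build_model(CNNConfig(), (30, 30, 1), 6)
        types = [type(l).__name__ for l in model.net.layers]
        assert types == ["Conv2D", "ReLU", "MaxPool2", "Conv2D", "ReLU",
                         "MaxPool2", "Flatten", "Dense", "ReLU", "Dense"]

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError, match="too small"):
            build_model(CNNConfig(), (6, 6, 1), 2)

    def test_same_seed_same_initial_weights(self):
        cfg = CNNConfig(conv_filters=(4, 4), dense_units=8, seed=5)
        a = build_model(cfg, (12, 12, 1), 2)
        b = build_model(cfg, (12, 12, 1), 2)
        for wa, wb in zip(a.net.get_weights(), b.net.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_gradient_matches_finite_differences(self, rng):
        """Backprop through the full stack agrees with numeric gradients."""
        from imucanvas import nn

        model = build_model(
            CNNConfig(conv_filters=(2, 2), dense_units=4, seed=0), (10, 10, 1), 2
        )
        x = rng.normal(size=(3, 10, 10, 1)).astype(np.float32)
        y = np.array([0, 1, 0])
        logits = model.net.forward(x)
        _, dlogits = nn.softmax_cross_entropy(logits, y)
        model.net.backward(dlogits)
        layer = model.net.layers[0]
        w = layer.params["W"]
        for idx in [(0, 0, 0, 0), (1, 2, 0, 1), (2, 1, 0, 0)]:
            eps = 1e-3
            orig = w[idx]
            w[idx] = orig + eps
            lp, _ = nn.softmax_cross_entropy(model.net.forward(x), y)
            w[idx] = orig - eps
            lm, _ = nn.softmax_cross_entropy(model.net.forward(x), y)
            w[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert layer.grads["W"][idx] == pytest.approx(numeric, abs=2e-3)


class TestTraining:
    def test_separable_data_reaches_high_train_accuracy(self, rng):
        images, labels = toy_images(rng)
        cfg = CNNConfig(conv_filters=(8, 8), dense_units=16, max_epochs=15,
                        patience=15, seed=0)
        res = train(cfg, images, labels, {"fractions": (0.8, 0.2)}, seed=0)
        model = res.models[0]
        train_acc = float((model.predict(images) == labels).mean())
        assert train_acc >= 0.99

    def test_degenerate_split_raises(self, rng):
        images = rng.integers(0, 255, size=(4, 12, 12)).astype(np.uint8)
        with pytest.raises(ValueError, match="degenerate"):
            train(CNNConfig(), images, ["a", "a", "a", "a"],
                  {"fractions": (0.5, 0.5)})

    def test_training_is_seed_reproducible(self, rng):
        images, labels = toy_images(rng, n_per_class=10)
        cfg = CNNConfig(conv_filters=(4, 4), dense_units=8, max_epochs=3,
                        patience=3, seed=9)
        r1 = train(cfg, images, labels, {"fractions": (0.8, 0.2)}, seed=9)
        r2 = train(cfg, images, labels, {"fractions": (0.8, 0.2)}, seed=9)
        assert r1.histories[0] == r2.histories[0]
        assert r1.confusion.counts == r2.confusion.counts

    def test_evaluate_returns_consistent_confusion(self, rng):
        images, labels = toy_images(rng, n_per_class=10)
        cfg = CNNConfig(conv_filters=(4, 4), dense_units=8, max_epochs=5,
                        patience=5, seed=2)
        res = train(cfg, images, labels, {"fractions": (0.8, 0.2)}, seed=2)
        conf, rep = evaluate(res.models[0], images, labels)
        assert conf.n_total == len(labels)
        assert 0.0 <= rep.overall_accuracy <= 1.0
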