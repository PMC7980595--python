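import numpy as np
import pytest

import enhseq as e
from enhseq import nets
from enhseq.models import build_network, load_model, save_model


def numeric_gradient_check(net, X, y, rtol=1e-4, n_checks=30, eps=1e-6):
    """Compare backprop gradients against central finite differences."""
    rng = np.random.default_rng(0)

    def loss_at():
        logits = net.forward(X, train=False)
        return nets.bce_with_logits(logits, y)[0]

    logits = net.forward(X, train=False)
    _, dlog = nets.bce_with_logits(logits, y)
    net.backward(dlog)
    analytic = [g.copy() for g in net.grads]
    for p, g in zip(net.params, analytic):
        flat_p = p.reshape(-1)
        flat_g = g.reshape(-1)
        idx = rng.choice(flat_p.size, size=min(n_checks, flat_p.size),
                         replace=False)
        for i in idx:
            orig = flat_p[i]
            flat_p[i] = orig + eps
            up = loss_at()
            flat_p[i] = orig - eps
            down = loss_at()
            flat_p[i] = orig
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(flat_g[i], rel=rtol, abs=1e-7)


def toy_separable(n=40, L=40, C=2, seed=0):
    """Positives are all-2.0 arrays, negatives all-0.5, plus small noise."""
    rng = np.random.default_rng(seed)
    Xp = 2.0 + 0.05 * rng.standard_normal((n // 2, L, C))
    Xn = 0.5 + 0.05 * rng.standard_normal((n // 2, L, C))
    X = np.concatenate([Xp, Xn])
    y = np.concatenate([np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)])
    return e.LabeledDataset(X, y)


class TestGradients:
    """Backprop of every layer family agrees with finite differences."""

    @pytest.mark.parametrize("arch", ["mlp", "cnn", "bilstm"])
    def test_network_gradients(self, arch):
        rng = np.random.default_rng(1)
        config = e.ModelConfig(
            arch=arch, mlp_hidden=(7, 5), cnn_filters=(4, 5), cnn_width=3,
            lstm_units=4, dense_units=5, dropout=0.0, seed=1)
        net = build_network(config, L=11, C=3, rng=rng)
        X = rng.standard_normal((6, 11, 3))
        y = np.array([1, 0, 1, 0, 1, 0])
        numeric_gradient_check(net, X, y)


class TestMakeFolds:
    def test_stratified_counts(self):
        ds = toy_separable(n=10)
        split = e.make_folds(ds, n_folds=5, seed=0)
        for fold in split.folds:
            test_labels = ds.y[fold["test"]]
            assert (test_labels == 1).sum() == 1
            assert (test_labels == 0).sum() == 1

    def test_partition_and_disjointness(self):
        ds = toy_separable(n=40)
        split = e.make_folds(ds, n_folds=5, seed=3)
        all_test = np.concatenate([f["test"] for f in split.folds])
        assert sorted(all_test) == list(range(40))
        for fold in split.folds:
            tr, va, te = (set(fold[k]) for k in ("train", "val", "test"))
            assert not (tr & va) and not (tr & te) and not (va & te)
            assert len(tr) + len(va) + len(te) == 40

    def test_rotating_validation_fold(self):
        ds = toy_separable(n=40)
        split = e.make_folds(ds, n_folds=5, seed=3)
        tests = [set(f["test"]) for f in split.folds]
        for f, fold in enumerate(split.folds):
            assert set(fold["val"]) == tests[(f + 1) % 5]

    def test_deterministic(self):
        ds = toy_separable(n=40)
        a = e.make_folds(ds, 5, seed=9)
        b = e.make_folds(ds, 5, seed=9)
        for fa, fb in zip(a.folds, b.folds):
            assert (fa["test"] == fb["test"]).all()

    def test_small_class_rejected(self):
        ds = e.LabeledDataset(np.zeros((6, 4, 2)),
                              np.array([1, 1, 1, 1, 0, 0]))
        with pytest.raises(ValueError):
            e.make_folds(ds, n_folds=5, seed=0)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            e.make_folds(toy_separable(), n_folds=2, seed=0)


class TestTrainModel:
    @pytest.mark.parametrize("arch", ["mlp", "cnn", "bilstm"])
    def test_separable_toy_reaches_perfect_training_accuracy(self, arch):
        ds = toy_separable(n=40, seed=1)
        config = e.ModelConfig(arch=arch, seed=0, batch_size=8)
        model = e.train_model(config, ds, ds)
        scores = model.predict(ds.X)
        assert e.accuracy(scores, ds.y) == 1.0
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_label_shuffle_gives_chance_validation_accuracy(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds = toy_separable(n=60, seed=seed)
            y_shuffled = rng.permutation(ds.y)
            shuffled = e.LabeledDataset(ds.X, y_shuffled)
            val = e.LabeledDataset(ds.X[::3], y_shuffled[::3])
            model = e.train_model(e.ModelConfig(arch="mlp", seed=seed),
                                  shuffled, val)
            accs.append(e.accuracy(model.predict(val.X), val.y))
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_swapped_labels_give_complementary_scores(self):
        ds = toy_separable(n=40, seed=2)
        flipped = e.LabeledDataset(ds.X, 1 - ds.y)
        config = e.ModelConfig(arch="mlp", dropout=0.0, seed=7)
        m = e.train_model(config, ds, ds)
        m_flip = e.train_model(config, flipped, flipped)
        s = m.predict(ds.X)
        s_flip = m_flip.predict(ds.X)
        assert np.max(np.abs(s_flip - (1 - s))) < 0.15

    def test_single_class_train_rejected(self):
        ds = toy_separable(n=20)
        pos_only = ds.subset(np.where(ds.y == 1)[0])
        with pytest.raises(ValueError, match="both classes"):
            e.train_model(e.ModelConfig(), pos_only, ds)

    def test_shape_mismatch_rejected(self):
        ds = toy_separable(n=20, L=40)
        other = toy_separable(n=20, L=30)
        with pytest.raises(ValueError, match="shape"):
            e.train_model(e.ModelConfig(), ds, other)
        model = e.train_model(e.ModelConfig(seed=0), ds, ds)
        with pytest.raises(ValueError, match="shape"):
            model.predict(other.X)

    def test_early_stopping_restores_best_checkpoint(self):
        ds = toy_separable(n=40, seed=3)
        model = e.train_model(e.ModelConfig(arch="mlp", seed=1), ds, ds)
        hist = model.history
        assert hist["best_val_loss"] <= hist["val_loss"][-1] + 1e-12
        assert hist["best_val_loss"] == min(hist["val_loss"])

    def test_deterministic_given_seed(self):
        ds = toy_separable(n=30, seed=4)
        config = e.ModelConfig(arch="mlp", seed=11)
        s1 = e.train_model(config, ds, ds).predict(ds.X)
        s2 = e.train_model(config, ds, ds).predict(ds.X)
        np.testing.assert_array_equal(s1, s2)


class TestPredict:
    def test_order_preserved_and_batch_consistency(self):
        ds = toy_separable(n=30, seed=5)
        model = e.train_model(e.ModelConfig(arch="mlp", seed=0), ds, ds)
        full = model.predict(ds.X)
        singles = np.concatenate([model.predict(ds.X[i:i + 1])
                                  for i in range(len(ds))])
        np.testing.assert_allclose(full, singles, atol=1e-12)

    def test_empty_input(self):
        ds = toy_separable(n=20)
        model = e.train_model(e.ModelConfig(arch="mlp", seed=0), ds, ds)
        assert model.predict([]).shape == (0,)

    def test_functional_predict_alias(self):
        ds = toy_separable(n=20)
        model = e.train_model(e.ModelConfig(arch="mlp", seed=0), ds, ds)
        np.testing.assert_array_equal(e.predict(model, ds.X),
                                      model.predict(ds.X))


class TestModelIO:
    @pytest.mark.parametrize("arch", ["mlp", "cnn", "bilstm"])
    def test_save_load_round_trip(self, tmp_path, arch):
        ds = toy_separable(n=24, seed=6)
        config = e.ModelConfig(arch=arch, lstm_units=4, cnn_filters=(3, 4),
                               mlp_hidden=(8, 4), dense_units=4, seed=0,
                               max_epochs=3)
        model = e.train_model(config, ds, ds)
        p = tmp_path / "m.npz"
        save_model(model, p)
        loaded = load_model(p)
        np.testing.assert_allclose(loaded.predict(ds.X), model.predict(ds.X))
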