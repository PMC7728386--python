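"""Architecture accounting, training engine correctness, ensembling."""

import numpy as np
import pytest

from voxstab.datasets import MutationTable
from voxstab.network import (
    ConvNet3D,
    ModelEnsemble,
    NetworkSpec,
    TrainConfig,
    count_parameters,
    load_ensemble,
    predict_ensemble,
    save_ensemble,
    train_ensemble,
    train_member,
)

from test_datasets import make_records
from voxstab.datasets import augment_reverse

TINY_SPEC = NetworkSpec(input_shape=(8, 8, 8, 14), conv_filters=(4, 6, 8),
                        dense_units=8, dropout_rate=0.5)


class TestCountParameters:
    def test_default_architecture_count(self):
        spec = NetworkSpec()
        assert count_parameters(spec) == 133_273
        assert ConvNet3D(spec).n_parameters() == 133_273

    def test_reduced_architecture_count(self):
        # 1516 + 654 + 1304 + 72 + 9
        assert count_parameters(TINY_SPEC) == 3_555
        assert ConvNet3D(TINY_SPEC).n_parameters() == 3_555

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(conv_filters=(0, 24, 32))
        with pytest.raises(ValueError):
            NetworkSpec(input_shape=(4, 4, 4, 14))  # conv stack underflows

    @pytest.mark.parametrize("edge", [8, 12, 16, 20])
    @pytest.mark.parametrize("filters,dense", [
        ((16, 24, 32), 24), ((8, 16, 24), 32), ((16, 24, 32), 64),
    ])
    def test_closed_form_matches_instantiated_model(self, edge, filters, dense):
        spec = NetworkSpec(input_shape=(edge, edge, edge, 14),
                           conv_filters=filters, dense_units=dense)
        assert count_parameters(spec) == ConvNet3D(spec).n_parameters()


class TestGradients:
    def test_backward_matches_numeric_gradient(self):
        spec = NetworkSpec(input_shape=(8, 8, 8, 2), conv_filters=(2, 2, 2),
                           dense_units=3, dropout_rate=0.0)
        model = ConvNet3D(spec, seed=0)
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        rng = np.random.default_rng(1)
        x = rng.random((2, 8, 8, 8, 2))
        y = rng.normal(size=2)

        def loss():
            pred, _ = model.forward(x)
            return float(np.mean((pred - y) ** 2))

        pred, cache = model.forward(x)
        grads = model.backward(2.0 * (pred - y) / len(y), cache)
        h = 1e-6
        rng_pick = np.random.default_rng(2)
        for key in model.params:
            flat = model.params[key].ravel()
            for idx in rng_pick.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss()
                flat[idx] = orig - h
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * h)
                analytic = grads[key].ravel()[idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), key


def _toy_data(n, spec, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    x = rng.random((n, *spec.input_shape), dtype=np.float32)
    if labels is None:
        labels = rng.normal(size=n)
    return x, np.asarray(labels, dtype=np.float64)


class TestTrainMember:
    def test_learns_a_constant_and_stops_early(self):
        spec = TINY_SPEC
        x, _ = _toy_data(40, spec, seed=0)
        y = np.full(40, 1.5)
        trained = train_member(x[:32], y[:32], x[32:], y[32:], spec,
                               TrainConfig(max_epochs=200, seed=0, learning_rate=0.05))
        assert trained.history["stopped_epoch"] < 200
        assert trained.best_val_mse < 0.05

    def test_early_stop_arithmetic_with_rising_validation_loss(self, monkeypatch):
        spec = TINY_SPEC
        x, y = _toy_data(20, spec, seed=1)
        counter = {"n": 0}

        def fake_predict(self, data, batch_size=64):
            counter["n"] += 1
            return np.full(len(data), float(counter["n"]))  # val MSE rises each epoch

        monkeypatch.setattr(ConvNet3D, "predict", fake_predict)
        trained = train_member(x[:16], y[:16], x[16:], np.zeros(4), spec,
                               TrainConfig(max_epochs=200, patience=10, seed=0))
        assert trained.history["stopped_epoch"] == 11
        assert trained.best_epoch == 1

    def test_keeps_best_validation_weights(self):
        spec = TINY_SPEC
        x, y = _toy_data(48, spec, seed=2)
        trained = train_member(x[:40], y[:40], x[40:], y[40:], spec,
                               TrainConfig(max_epochs=15, seed=3))
        best = trained.best_epoch
        assert trained.history["val_mse"][best - 1] == min(trained.history["val_mse"])
        # restored weights reproduce the recorded best MSE
        val_mse = float(np.mean((trained.model.predict(x[40:]) - y[40:]) ** 2))
        assert val_mse == pytest.approx(trained.best_val_mse, rel=1e-5)

    def test_empty_split_rejected(self):
        x, y = _toy_data(4, TINY_SPEC)
        with pytest.raises(ValueError):
            train_member(x, y, x[:0], y[:0], TINY_SPEC, TrainConfig())

    def test_deterministic_given_seed(self):
        x, y = _toy_data(24, TINY_SPEC, seed=4)
        cfg = TrainConfig(max_epochs=4, seed=9)
        t1 = train_member(x[:20], y[:20], x[20:], y[20:], TINY_SPEC, cfg)
        t2 = train_member(x[:20], y[:20], x[20:], y[20:], TINY_SPEC, cfg)
        assert t1.history["val_mse"] == t2.history["val_mse"]
        for key in t1.model.params:
            np.testing.assert_array_equal(t1.model.params[key], t2.model.params[key])

    def test_inference_is_repeatable(self):
        x, y = _toy_data(16, TINY_SPEC, seed=5)
        trained = train_member(x[:12], y[:12], x[12:], y[12:], TINY_SPEC,
                               TrainConfig(max_epochs=2, seed=0))
        p1 = trained.model.predict(x)
        p2 = trained.model.predict(x)
        np.testing.assert_array_equal(p1, p2)


def _constant_member(spec, value):
    model = ConvNet3D(spec, seed=0)
    for key in model.params:
        model.params[key] = np.zeros_like(model.params[key])
    model.params["bo"] = np.array([value], dtype=np.float32)
    from voxstab.network import TrainedModel
    return TrainedModel(model=model, history={"best_epoch": 1, "best_val_mse": 0.0})


class TestEnsemble:
    def test_mean_of_member_outputs(self):
        spec = TINY_SPEC
        members = [_constant_member(spec, float(v)) for v in range(1, 11)]
        ens = ModelEnsemble(members=members, val_subsets=[[i] for i in range(10)],
                            spec=spec)
        x = np.zeros((3, *spec.input_shape), dtype=np.float32)
        np.testing.assert_allclose(predict_ensemble(ens, x), 5.5)

    def test_single_member_passthrough_and_permutation_invariance(self):
        spec = TINY_SPEC
        x = np.zeros((2, *spec.input_shape), dtype=np.float32)
        one = ModelEnsemble(members=[_constant_member(spec, 2.5)],
                            val_subsets=[[0]], spec=spec)
        np.testing.assert_allclose(predict_ensemble(one, x), 2.5)
        members = [_constant_member(spec, float(v)) for v in (1, 4, 7)]
        a = ModelEnsemble(members=members, val_subsets=[[0], [1], [2]], spec=spec)
        b = ModelEnsemble(members=members[::-1], val_subsets=[[2], [1], [0]], spec=spec)
        np.testing.assert_allclose(predict_ensemble(a, x), predict_ensemble(b, x))

    def test_shape_mismatch_rejected(self):
        ens = ModelEnsemble(members=[_constant_member(TINY_SPEC, 1.0)],
                            val_subsets=[[0]], spec=TINY_SPEC)
        with pytest.raises(ValueError, match="shape"):
            predict_ensemble(ens, np.zeros((2, 8, 8, 8, 7), dtype=np.float32))

    def test_members_validate_on_disjoint_covering_subsets(self):
        table = augment_reverse(make_records(8, seed=0))
        rng = np.random.default_rng(0)
        grids = rng.random((len(table), 8, 8, 8, 14), dtype=np.float32)
        ens = train_ensemble(table, grids, spec=TINY_SPEC,
                             config=TrainConfig(max_epochs=2, seed=1), k=2)
        assert len(ens.members) == 2
        flat = sorted(i for s in ens.val_subsets for i in s)
        assert flat == list(range(len(table)))
        assert set(ens.val_subsets[0]).isdisjoint(ens.val_subsets[1])

    def test_ensemble_training_is_deterministic(self):
        table = augment_reverse(make_records(6, seed=2))
        rng = np.random.default_rng(3)
        grids = rng.random((len(table), 8, 8, 8, 14), dtype=np.float32)
        cfg = TrainConfig(max_epochs=3, seed=5)
        e1 = train_ensemble(table, grids, spec=TINY_SPEC, config=cfg, k=2)
        e2 = train_ensemble(table, grids, spec=TINY_SPEC, config=cfg, k=2)
        assert [m.best_epoch for m in e1.members] == [m.best_epoch for m in e2.members]
        assert e1.best_val_mses == e2.best_val_mses

    def test_save_load_round_trip(self, tmp_path):
        table = augment_reverse(make_records(6, seed=4))
        rng = np.random.default_rng(5)
        grids = rng.random((len(table), 8, 8, 8, 14), dtype=np.float32)
        ens = train_ensemble(table, grids, spec=TINY_SPEC,
                             config=TrainConfig(max_epochs=2, seed=0), k=2)
        save_ensemble(ens, tmp_path / "models")
        back = load_ensemble(tmp_path / "models")
        x = rng.random((4, 8, 8, 8, 14), dtype=np.float32)
        np.testing.assert_allclose(predict_ensemble(ens, x),
                                   predict_ensemble(back, x), atol=1e-6)
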