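"""Surrogate training protocol, metric definitions, and model persistence."""

import numpy as np
import pandas as pd
import pytest

import gradientforge as gf
from gradientforge.dataset import INPUT_COLUMNS, PROFILE_COLUMNS


def _make_dataset(X, Y, species="O2"):
    frame = pd.DataFrame(
        np.column_stack([X, Y]), columns=INPUT_COLUMNS + PROFILE_COLUMNS
    )
    return gf.GradientDataset(species=species, frame=frame)


class TestSplitDataset:
    @pytest.mark.parametrize("n, sizes", [(10_000, (6500, 1500, 2000)),
                                          (100, (65, 15, 20))])
    def test_fraction_arithmetic(self, n, sizes):
        rng = np.random.default_rng(0)
        ds = _make_dataset(rng.random((n, 4)), rng.random((n, 20)))
        tr, va, te = gf.split_dataset(ds, gf.SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == sizes

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(1)
        ds = _make_dataset(rng.random((97, 4)), rng.random((97, 20)))
        tr, va, te = gf.split_dataset(ds, gf.SplitSpec(seed=2))
        parts = pd.concat([tr.frame, va.frame, te.frame])
        assert len(parts) == 97
        merged = parts.sort_values(INPUT_COLUMNS).reset_index(drop=True)
        original = ds.frame.sort_values(INPUT_COLUMNS).reset_index(drop=True)
        assert merged.equals(original)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            gf.SplitSpec(train=0.6, val=0.2, test=0.3)

    def test_too_small_dataset_rejected(self):
        rng = np.random.default_rng(2)
        ds = _make_dataset(rng.random((10, 4)), rng.random((10, 20)))
        with pytest.raises(ValueError):
            gf.split_dataset(ds, gf.SplitSpec())


class TestTrain:
    def test_constant_profiles_are_learned_exactly(self):
        rng = np.random.default_rng(3)
        X = rng.uniform([0.2, 1, 0.2, 1], [0.6, 100, 10, 150], size=(120, 4))
        Y = np.full((120, 20), 0.123)
        tr = _make_dataset(X[:90], Y[:90])
        va = _make_dataset(X[90:], Y[90:])
        model = gf.train(
            tr, va,
            gf.TrainConfig(epochs=3000, batch_size=90, learning_rate=5e-3, seed=4),
        )
        assert gf.evaluate(model, tr).amse < 1e-8

    def test_fixed_seed_gives_identical_weights(self, small_pt_dataset):
        tr, va, _ = gf.split_dataset(small_pt_dataset, gf.SplitSpec(seed=5))
        cfg = gf.TrainConfig(epochs=5, seed=6)
        m1, m2 = gf.train(tr, va, cfg), gf.train(tr, va, cfg)
        for W1, W2 in zip(m1.coefs, m2.coefs):
            assert np.array_equal(W1, W2)
        assert m1.training_log.equals(m2.training_log)

    def test_training_log_has_one_row_per_epoch(self, small_o2_model):
        log = small_o2_model.training_log
        assert list(log.columns) == ["epoch", "train_amse_mM2", "val_amse_mM2"]
        assert len(log) == small_o2_model.config.epochs

    def test_no_overfitting_at_small_scale(self, small_o2_model):
        # validation error tracks training error (no large generalization gap)
        last = small_o2_model.training_log.iloc[-1]
        assert last.val_amse_mM2 <= 2.0 * last.train_amse_mM2 + 1e-6

    def test_accuracy_comparable_to_reference_mlp_library(self, small_pt_dataset):
        # independent cross-check of the trainer: scikit-learn's MLP on the
        # same data and budget should land in the same accuracy regime
        from sklearn.neural_network import MLPRegressor

        tr, va, te = gf.split_dataset(small_pt_dataset, gf.SplitSpec(seed=31))
        mine = gf.train(tr, va, gf.TrainConfig(epochs=120, seed=32))
        my_amse = gf.evaluate(mine, te).amse

        X, Y = tr.X, tr.Y
        xm, xs = X.mean(0), X.std(0)
        ref = MLPRegressor(hidden_layer_sizes=(64, 64), solver="adam",
                           batch_size=32, max_iter=120, random_state=32)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref.fit((X - xm) / xs, Y)
        ref_amse = np.mean((ref.predict((te.X - xm) / xs) - te.Y) ** 2)
        assert my_amse < 3.0 * ref_amse

    def test_empty_split_rejected(self, small_pt_dataset):
        empty = small_pt_dataset.subset([])
        with pytest.raises(ValueError):
            gf.train(empty, small_pt_dataset, gf.TrainConfig(epochs=1))


class TestPredictProfile:
    def test_prediction_shape_and_bounds(self, small_o2_model):
        profile = gf.predict_profile(small_o2_model, 0.5, gf.Morphology(30, 3, 50))
        assert len(profile.c_mM) == 20
        assert np.all(profile.c_mM >= 0.0)
        assert np.all(profile.c_mM <= 0.246)

    def test_prediction_is_deterministic(self, small_o2_model):
        m = gf.Morphology(30, 3, 50)
        a = gf.predict_profile(small_o2_model, 0.5, m)
        b = gf.predict_profile(small_o2_model, 0.5, m)
        assert np.array_equal(a.c_mM, b.c_mM)

    def test_out_of_range_inputs_warn_but_predict(self, small_o2_model):
        X = [[0.9, 30.0, 3.0, 50.0]]  # potential beyond the training window
        with pytest.warns(UserWarning, match="training ranges"):
            y = small_o2_model.predict_batch(X)
        assert y.shape == (1, 20)


class TestEvaluate:
    def test_perfect_prediction_scores_perfectly(self, small_pt_dataset):
        class Oracle:
            species = "O2"

            def predict_batch(self, X, warn_out_of_range=False):
                return small_pt_dataset.Y[: len(np.atleast_2d(X))]

        report = gf.evaluate(Oracle(), small_pt_dataset)
        assert report.amse == 0.0 and report.sd == 0.0 and report.r2 == 1.0

    def test_uniform_offset_closed_form(self, small_pt_dataset):
        class Offset:
            species = "H2O2"  # avoid the O2 upper clip

            def predict_batch(self, X, warn_out_of_range=False):
                return small_pt_dataset.Y[: len(np.atleast_2d(X))] + 0.01

        report = gf.evaluate(Offset(), small_pt_dataset)
        assert report.amse == pytest.approx(1e-4, rel=1e-9)
        assert report.sd == pytest.approx(0.0, abs=1e-18)

    def test_two_row_hand_computed_oracle(self):
        # spreadsheet-style oracle on a 2 x 20 table
        Y = np.vstack([np.full(20, 0.10), np.linspace(0.0, 0.19, 20)])
        pred = Y + np.vstack([np.full(20, 0.02), np.full(20, -0.01)])
        mse_rows = [0.02**2, 0.01**2]
        amse = np.mean(mse_rows)
        sd = np.sqrt(np.mean((np.array(mse_rows) - amse) ** 2))

        X = np.tile([0.5, 30.0, 3.0, 50.0], (2, 1))
        ds = _make_dataset(X, Y, species="H2O2")

        class Fixed:
            species = "H2O2"

            def predict_batch(self, X, warn_out_of_range=False):
                return pred

        report = gf.evaluate(Fixed(), ds)
        assert report.amse == pytest.approx(amse, rel=1e-12)
        assert report.sd == pytest.approx(sd, rel=1e-12)
        np.testing.assert_allclose(report.row_mse, mse_rows, rtol=1e-12)


class TestPersistence:
    def test_save_load_predict_is_bit_identical(self, small_o2_model, tmp_path):
        small_o2_model.save(tmp_path / "model")
        loaded = gf.SurrogateModel.load(tmp_path / "model")
        X = np.array([[0.5, 30, 3, 50], [0.3, 80, 8, 120]])
        assert np.array_equal(
            small_o2_model.predict_batch(X), loaded.predict_batch(X)
        )
        assert loaded.species == "O2"
        assert loaded.config == small_o2_model.config
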