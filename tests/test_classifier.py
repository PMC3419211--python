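"""Scaling, grid search and RBF-SVM train/predict contracts."""

import numpy as np
import pytest

from hgtident.classifier import (
    SvmConfig,
    TrainedModel,
    apply_scaler,
    fit_scaler,
    grid_search,
    predict,
    train,
)
from hgtident.dataset import LabeledDataset
from hgtident.metrics import ConfusionCounts, recall

from .conftest import gaussian_dataset


class TestScaler:
    def test_maps_min_max_to_unit_interval(self):
        X = np.zeros((2, 15))
        X[:, 0] = [2.0, 4.0]
        p = fit_scaler(X)
        np.testing.assert_allclose(p.transform(X)[:, 0], [-1.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        X = np.full((3, 15), 3.0)
        p = fit_scaler(X)
        np.testing.assert_allclose(p.transform(X), 0.0)

    def test_out_of_range_extrapolates(self):
        X = np.zeros((2, 15))
        X[:, 0] = [0.0, 10.0]
        p = fit_scaler(X)
        test = np.zeros((1, 15))
        test[0, 0] = 12.0
        assert p.transform(test)[0, 0] == pytest.approx(1.4)

    def test_idempotent_on_scaled_training_data(self):
        ds = gaussian_dataset(0)
        p = fit_scaler(ds)
        once = apply_scaler(p, ds)
        twice = apply_scaler(fit_scaler(once), once)
        np.testing.assert_allclose(once.X, twice.X, atol=1e-12)


class TestGridSearch:
    def test_single_point_grid(self):
        ds = gaussian_dataset(1)
        cfg = SvmConfig(c_grid=(2.0,), g_grid=(0.5,), seed=0)
        assert grid_search(ds, cfg) == (2.0, 0.5)

    def test_separable_data_reaches_full_recall(self):
        ds = gaussian_dataset(2, shift=8.0, informative=tuple(range(15)))
        cfg = SvmConfig(c_grid=(1.0, 100.0), g_grid=(0.01, 0.1), seed=0)
        c, g = grid_search(ds, cfg)
        model = train(ds, c, g)
        cc = ConfusionCounts.from_labels(ds.y, predict(model, ds))
        assert recall(cc) == 100.0

    def test_grid_order_does_not_matter(self):
        ds = gaussian_dataset(3)
        a = grid_search(ds, SvmConfig(c_grid=(1.0, 4.0, 16.0), g_grid=(0.01, 0.1), seed=5))
        b = grid_search(ds, SvmConfig(c_grid=(16.0, 1.0, 4.0), g_grid=(0.1, 0.01), seed=5))
        assert a == b

    def test_single_class_is_error(self):
        ds = gaussian_dataset(4)
        ds.y[:] = 1
        with pytest.raises(ValueError):
            grid_search(ds, SvmConfig(c_grid=(1.0,), g_grid=(0.1,)))


class TestTrainPredict:
    def test_separated_gaussians_high_heldout_recall(self):
        train_ds = gaussian_dataset(5, n_neg=150, n_pos=150, shift=5.0,
                                    informative=tuple(range(15)))
        test_ds = gaussian_dataset(6, n_neg=150, n_pos=150, shift=5.0,
                                   informative=tuple(range(15)))
        model = train(train_ds, c=8.0, g=1.0 / 15)
        cc = ConfusionCounts.from_labels(test_ds.y, predict(model, test_ds))
        assert recall(cc) >= 99.0

    def test_memorization_at_large_c(self):
        ds = gaussian_dataset(7)
        model = train(ds, c=1e6, g=1.0)
        cc = ConfusionCounts.from_labels(ds.y, predict(model, ds))
        assert recall(cc) == 100.0

    def test_round_trip_identical_predictions(self, tmp_path):
        ds = gaussian_dataset(8)
        model = train(ds, c=2.0, g=0.1)
        path = tmp_path / "model.pkl"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(predict(model, ds), predict(loaded, ds))

    def test_predictions_invariant_to_row_order(self):
        ds = gaussian_dataset(9)
        model = train(ds, c=2.0, g=0.1)
        perm = np.random.default_rng(0).permutation(ds.n_genes)
        shuffled = ds.subset_rows(perm)
        np.testing.assert_array_equal(predict(model, shuffled), predict(model, ds)[perm])

    def test_empty_mask_is_error(self):
        ds = gaussian_dataset(10)
        with pytest.raises(ValueError):
            train(ds, c=1.0, g=0.1, mask=np.zeros(15, dtype=bool))

    def test_dropping_pure_noise_feature_does_not_degrade(self):
        """Held-out recall with a noise feature removed stays within noise."""
        deltas = []
        for seed in range(10):
            tr = gaussian_dataset(seed, shift=2.0)
            te = gaussian_dataset(100 + seed, shift=2.0)
            full = train(tr, c=8.0, g=0.1)
            mask = np.ones(15, dtype=bool)
            mask[14] = False  # pure-noise column
            reduced = train(tr, c=8.0, g=0.1, mask=mask)
            r_full = recall(ConfusionCounts.from_labels(te.y, predict(full, te)))
            r_red = recall(ConfusionCounts.from_labels(te.y, predict(reduced, te)))
            deltas.append(r_red - r_full)
        assert np.mean(deltas) > -5.0
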