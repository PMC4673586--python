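"""Grid-searched RBF-SVM, k-fold and jackknife cross-validation."""

import numpy as np
import pytest

from ggaplect import (
    ProteinSequence,
    RBFGridSVC,
    SVMConfig,
    grid_search_train,
    jackknife_cv,
    kfold_cv,
    load_model,
    save_model,
)
from ggaplect.svm import default_c_grid, default_gamma_grid, predict


@pytest.fixture
def separable():
    """Two tight, well-separated Gaussian clusters."""
    rng = np.random.default_rng(0)
    X = np.vstack(
        [rng.normal(0, 0.05, (12, 4)), rng.normal(1, 0.05, (12, 4))]
    )
    y = np.array([1] * 12 + [0] * 12)
    return X, y


SMALL = SVMConfig(
    c_grid=2.0 ** np.arange(-2, 9, 2),
    gamma_grid=2.0 ** np.arange(-9, 0, 2),
    tuning_folds=4,
    seed=0,
)


class TestSVMConfig:
    def test_default_grids(self):
        cfg = SVMConfig()
        np.testing.assert_allclose(cfg.c_grid[0], 2.0**-5)
        np.testing.assert_allclose(cfg.c_grid[-1], 2.0**15)
        assert cfg.c_grid.size == 21
        np.testing.assert_allclose(cfg.gamma_grid[0], 2.0**-15)
        np.testing.assert_allclose(cfg.gamma_grid[-1], 2.0**-5)
        assert cfg.gamma_grid.size == 11
        assert np.all(np.diff(cfg.c_grid) > 0) and np.all(cfg.c_grid > 0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            SVMConfig(c_grid=np.array([-1.0, 1.0]))


class TestGridSearch:
    def test_separable_reaches_perfect_training_accuracy(self, separable):
        X, y = separable
        model, report = grid_search_train(X, y, SMALL)
        assert np.array_equal(model.svc.predict(X), y)
        assert len(report) == SMALL.c_grid.size * SMALL.gamma_grid.size

    def test_deterministic_selection(self, separable):
        X, y = separable
        m1, _ = grid_search_train(X, y, SMALL)
        m2, _ = grid_search_train(X, y, SMALL)
        assert (m1.c, m1.gamma) == (m2.c, m2.gamma)

    def test_tie_break_prefers_smaller_c_then_gamma(self, separable):
        # separable data: many pairs reach 100% CV accuracy; the winner
        # must be the first in (c asc, gamma asc) order among them
        X, y = separable
        clf = RBFGridSVC(
            c_grid=SMALL.c_grid, gamma_grid=SMALL.gamma_grid,
            tuning_folds=4, random_state=0,
        ).fit(X, y)
        top = clf.grid_scores_[
            clf.grid_scores_.cv_accuracy == clf.best_cv_accuracy_
        ].sort_values(["c", "gamma"]).iloc[0]
        assert (clf.best_c_, clf.best_gamma_) == (top.c, top.gamma)

    def test_too_many_folds_suggests_fewer(self):
        X = np.random.default_rng(1).random((6, 3))
        y = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="folds"):
            RBFGridSVC(tuning_folds=4).fit(X, y)


class TestKFold:
    def test_fixed_seed_reproducible(self, separable):
        X, y = separable
        r1 = kfold_cv(X, y, 4, c=1.0, gamma=0.5, seed=3)
        r2 = kfold_cv(X, y, 4, c=1.0, gamma=0.5, seed=3)
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)

    def test_k_equal_n_reduces_to_jackknife(self, separable):
        X, y = separable
        r_k = kfold_cv(X, y, len(y), c=1.0, gamma=0.5, seed=0)
        r_j = jackknife_cv(X, y, c=1.0, gamma=0.5)
        np.testing.assert_array_equal(r_k.y_pred, r_j.y_pred)

    def test_k_exceeding_class_size_rejected(self, separable):
        X, y = separable
        with pytest.raises(ValueError, match="folds"):
            kfold_cv(X, y, 13, c=1.0, gamma=0.5)


class TestJackknife:
    def test_four_sample_fold_structure(self):
        # each of the 4 rounds trains on exactly 3 samples
        from sklearn.svm import SVC

        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([1, 1, 0, 0])
        seen = []
        orig_fit = SVC.fit

        def spy(self, Xf, yf, **kw):
            seen.append(len(yf))
            return orig_fit(self, Xf, yf, **kw)

        SVC.fit = spy
        try:
            res = jackknife_cv(X, y, c=10.0, gamma=1.0)
        finally:
            SVC.fit = orig_fit
        assert seen == [3, 3, 3, 3]
        assert res.y_pred.shape == (4,)

    def test_order_invariance(self, separable):
        X, y = separable
        res = jackknife_cv(X, y, c=1.0, gamma=0.5)
        perm = np.random.default_rng(2).permutation(len(y))
        res_p = jackknife_cv(X[perm], y[perm], c=1.0, gamma=0.5)
        np.testing.assert_array_equal(res.y_pred[perm], res_p.y_pred)

    def test_duplicating_samples_keeps_separable_accuracy(self):
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        y = np.array([1, 1, 1, 0, 0, 0])
        base = jackknife_cv(X, y, c=10.0, gamma=1.0).metrics.acc
        dup = jackknife_cv(
            np.vstack([X, X]), np.concatenate([y, y]), c=10.0, gamma=1.0
        ).metrics.acc
        assert dup >= base

    def test_minimum_class_size_enforced(self):
        X = np.array([[0.0], [1.0], [1.1]])
        y = np.array([1, 0, 0])
        with pytest.raises(ValueError):
            jackknife_cv(X, y, c=1.0, gamma=1.0)


class TestPredictAndSerialization:
    def test_sequence_prediction_with_per_record_errors(self, planted_dataset):
        from ggaplect import encode_dataset, rank_features

        spec, dataset, _ = planted_dataset
        mat = encode_dataset(dataset, spec.gap)
        table = rank_features(mat)
        cols = table.order[:30]
        model, _ = grid_search_train(
            mat.X[:, cols], mat.labels, SMALL, gap=spec.gap, feature_indices=cols
        )
        queries = [dataset.sequences[0], ProteinSequence("tiny", "AC")]
        records = predict(model, queries)
        assert records[0].error is None and records[0].label in (0, 1)
        assert records[1].error is not None and records[1].label is None

    def test_save_load_round_trip(self, separable, tmp_path):
        X, y = separable
        model, _ = grid_search_train(X, y, SMALL)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        assert (back.c, back.gamma) == (model.c, model.gamma)
        np.testing.assert_array_equal(back.svc.predict(X), model.svc.predict(X))

    def test_missing_model_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "absent.joblib")

    def test_dimension_mismatch_fails_loudly(self, separable):
        X, y = separable
        model, _ = grid_search_train(X, y, SMALL, gap=1, feature_indices=None)
        # model expects 4 features; a real sequence encodes to 400
        with pytest.raises(ValueError, match="dimension mismatch"):
            predict(model, [ProteinSequence("q", "ACDEFGHIKL")])
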