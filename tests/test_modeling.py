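"""Splitting, cross-validation grid, selection, training, and prediction."""

import numpy as np
import pandas as pd
import pytest

from cannaspec.modeling import (
    CLASSIFIERS,
    ModelBundle,
    boundary_sensitivity_scan,
    cross_validate_grid,
    make_classifier,
    predict,
    predict_scores,
    select_best,
    SelectionGrid,
    spectral_matrix,
    split_dataset,
    train_final,
)
from cannaspec.preprocessing import PREPROCESS_METHODS
from cannaspec.segmentation import spectrum_columns


def make_table(n_per_class=60, n_bands=24, classes=("a", "b", "c"), noise=0.02, seed=0):
    """Separable toy spectra: one Gaussian bump per class along the band axis."""
    rng = np.random.default_rng(seed)
    rows = []
    grid = np.arange(n_bands)
    for i, cls in enumerate(classes):
        center = n_bands * (i + 1) / (len(classes) + 1)
        bump = 0.2 + 0.6 * np.exp(-(((grid - center) / 3.0) ** 2))
        spectra = bump + rng.normal(0, noise, size=(n_per_class, n_bands))
        for s in spectra:
            rows.append({"label": cls, **dict(zip(spectrum_columns(n_bands), s))})
    return pd.DataFrame(rows).sample(frac=1.0, random_state=seed).reset_index(drop=True)


class TestSplit:
    def test_ten_rows_split_eight_two(self):
        table = make_table(n_per_class=5, classes=("a", "b"))
        cal, pred = split_dataset(table, 0.2, seed=0)
        assert len(cal) == 8 and len(pred) == 2

    def test_ceiling_rounding_reproduces_reference_count(self):
        table = pd.DataFrame({"x": np.zeros(4707)})
        cal, pred = split_dataset(table, 0.2, seed=1)
        assert len(pred) == 942 and len(cal) == 3765

    def test_same_seed_same_split(self):
        table = make_table()
        c1, p1 = split_dataset(table, 0.2, seed=5)
        c2, p2 = split_dataset(table, 0.2, seed=5)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_disjoint_and_exhaustive(self):
        table = make_table(n_per_class=20)
        table["row_id"] = np.arange(len(table))
        cal, pred = split_dataset(table, 0.2, seed=3)
        ids = set(cal["row_id"]) | set(pred["row_id"])
        assert len(ids) == len(table)
        assert not (set(cal["row_id"]) & set(pred["row_id"]))

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_dataset(pd.DataFrame({"x": [1, 2]}), 0.2, 0)


class TestCrossValidateGrid:
    def test_separable_two_class_lr_is_perfect(self):
        table = make_table(n_per_class=40, classes=("a", "b"))
        grid = cross_validate_grid(
            table, {"label": "label"}, seed=0, methods=("raw",), classifiers=("LR",)
        )
        assert grid.accuracies["label"].loc["raw", "LR"] == 1.0

    def test_grid_shape_is_5x5(self):
        table = make_table(n_per_class=25, classes=("a", "b"))
        grid = cross_validate_grid(table, {"label": "label"}, seed=0)
        acc = grid.accuracies["label"]
        assert acc.shape == (5, 5)
        assert tuple(acc.index) == PREPROCESS_METHODS
        assert tuple(acc.columns) == CLASSIFIERS
        assert ((acc.values >= 0) & (acc.values <= 1)).all()

    def test_shuffled_labels_score_at_chance(self):
        rng = np.random.default_rng(0)
        n = 450
        table = pd.DataFrame(
            rng.normal(size=(n, 8)), columns=spectrum_columns(8)
        )
        table["label"] = np.repeat(["a", "b", "c"], n // 3)
        table["label"] = rng.permutation(table["label"].to_numpy())
        grid = cross_validate_grid(
            table, {"label": "label"}, seed=0, methods=("raw",), classifiers=("LR",)
        )
        assert grid.accuracies["label"].loc["raw", "LR"] == pytest.approx(1 / 3, abs=0.08)

    def test_small_class_error_names_the_class(self):
        table = make_table(n_per_class=30, classes=("a", "b"))
        table.loc[table["label"] == "b", "label"] = "a"
        table.loc[table.index[:4], "label"] = "rare"
        with pytest.raises(ValueError, match="rare"):
            cross_validate_grid(table, {"label": "label"}, seed=0)

    def test_msc_reference_fitted_inside_each_fold(self):
        """Leakage audit: each fold's MSC reference equals the mean of that
        fold's training rows only."""
        table = make_table(n_per_class=30, classes=("a", "b"))
        grid = cross_validate_grid(
            table, {"label": "label"}, seed=0, methods=("msc",), classifiers=("GNB",)
        )
        X = spectral_matrix(table)
        assert len(grid.fold_msc_references) == 10
        for fold_id, (tr, _va) in enumerate(grid.folds):
            assert np.allclose(grid.fold_msc_references[fold_id], X[tr].mean(axis=0))
        global_mean = X.mean(axis=0)
        assert not any(
            np.allclose(ref, global_mean) for ref in grid.fold_msc_references.values()
        )


class TestSelection:
    def _grid(self, tables):
        return SelectionGrid(accuracies=tables, folds=[], seed=0)

    def test_unique_maximum_wins(self):
        acc = pd.DataFrame(0.5, index=list(PREPROCESS_METHODS), columns=list(CLASSIFIERS))
        acc.loc["msc", "KNN"] = 0.9
        assert select_best(self._grid({"q": acc}))["q"] == ("msc", "KNN")

    def test_all_equal_resolves_to_raw_lr(self):
        acc = pd.DataFrame(0.8, index=list(PREPROCESS_METHODS), columns=list(CLASSIFIERS))
        assert select_best(self._grid({"q": acc}))["q"] == ("raw", "LR")

    def test_tie_breaks_by_method_before_classifier(self):
        acc = pd.DataFrame(0.1, index=list(PREPROCESS_METHODS), columns=list(CLASSIFIERS))
        acc.loc["sg", "RF"] = 0.9
        acc.loc["der1", "LR"] = 0.9
        assert select_best(self._grid({"q": acc}))["q"] == ("sg", "RF")


class TestTrainPredict:
    def test_retraining_is_deterministic(self):
        table = make_table()
        fixed = spectral_matrix(make_table(seed=9))
        b1 = train_final(table, "label", ("msc", "RF"), seed=4)
        b2 = train_final(table, "label", ("msc", "RF"), seed=4)
        assert np.array_equal(predict(b1, fixed), predict(b2, fixed))

    def test_bundle_round_trip_preserves_predictions(self, tmp_path):
        table = make_table()
        bundle = train_final(table, "label", ("msc", "LR"), seed=0)
        bundle.save(tmp_path / "m.joblib")
        loaded = ModelBundle.load(tmp_path / "m.joblib")
        X = spectral_matrix(table)
        assert np.array_equal(predict(bundle, X), predict(loaded, X))
        assert loaded.method == "msc" and loaded.quality == "label"

    def test_training_points_of_separable_set_recovered(self):
        table = make_table(noise=0.01)
        bundle = train_final(table, "label", ("raw", "KNN"), seed=0)
        assert (predict(bundle, spectral_matrix(table)) == table["label"]).all()

    def test_constant_batch_gets_constant_label(self):
        table = make_table()
        bundle = train_final(table, "label", ("raw", "LR"), seed=0)
        X = np.tile(spectral_matrix(table)[3], (5, 1))
        assert len(set(predict(bundle, X))) == 1

    def test_probabilities_normalized(self):
        table = make_table()
        bundle = train_final(table, "label", ("sg", "LR"), seed=0)
        _, scores = predict_scores(bundle, spectral_matrix(table)[:20])
        assert np.allclose(scores.sum(axis=1), 1.0)
        assert (scores >= 0).all()

    def test_lr_probabilities_match_sigmoid_closed_form(self):
        """Per-class one-vs-rest probability equals 1/(1+exp(-(b0 + X.w)))
        recomputed from the stored coefficients."""
        table = make_table(classes=("a", "b", "c"))
        bundle = train_final(table, "label", ("raw", "LR"), seed=0)
        X = spectral_matrix(table)[:15]
        ovr = bundle.classifier
        for est in ovr.estimators_:
            z = est.intercept_[0] + X @ est.coef_[0]
            assert np.allclose(est.predict_proba(X)[:, 1], 1.0 / (1.0 + np.exp(-z)))

    def test_band_count_mismatch(self):
        table = make_table(n_bands=24)
        bundle = train_final(table, "label", ("raw", "LR"), seed=0)
        with pytest.raises(ValueError, match="bands"):
            predict(bundle, np.zeros((2, 10)))

    def test_svm_scores_come_from_decision_function(self):
        table = make_table(classes=("a", "b"))
        bundle = train_final(table, "label", ("raw", "SVM"), seed=0)
        labels, scores = predict_scores(bundle, spectral_matrix(table)[:10])
        assert scores.shape == (10, 2)
        assert (labels == np.array(bundle.class_order)[scores.argmax(axis=1)]).all()


class TestBoundaryScan:
    def make_quantity_table(self, thresholds=(30.0, 70.0), n=400, seed=0):
        """Spectra switch between three latent states at known thresholds."""
        rng = np.random.default_rng(seed)
        q = rng.uniform(0.5, 100.0, size=n)
        grid = np.arange(16)
        states = [0.2 + 0.6 * np.exp(-(((grid - c) / 2.5) ** 2)) for c in (3, 8, 13)]
        rows = []
        for qi in q:
            state = states[int(np.digitize(qi, thresholds, right=True))]
            rows.append(dict(zip(spectrum_columns(16), state + rng.normal(0, 0.03, 16))))
        table = pd.DataFrame(rows)
        table["quantity"] = q
        return table

    def test_recovers_generating_thresholds(self):
        table = self.make_quantity_table()
        candidates = [(20.0, 60.0), (30.0, 70.0), (45.0, 85.0)]
        result = boundary_sensitivity_scan(table, "quantity", candidates, seed=0)
        best = result.loc[result["accuracy"].idxmax()]
        assert best["boundaries"] == (30.0, 70.0)
        assert best["accuracy"] > 0.95

    def test_degenerate_candidate_skipped_with_note(self):
        table = self.make_quantity_table(n=120)
        result = boundary_sensitivity_scan(
            table, "quantity", [(99.8, 99.9), (30.0, 70.0)], seed=0
        )
        assert bool(result.loc[0, "skipped"])
        assert "class" in result.loc[0, "note"]
        assert not bool(result.loc[1, "skipped"])

    def test_quantity_out_of_range_rejected(self):
        table = self.make_quantity_table(n=50)
        table.loc[0, "quantity"] = -2.0
        with pytest.raises(ValueError, match="quantity"):
            boundary_sensitivity_scan(table, "quantity", [(30.0, 70.0)], seed=0)
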