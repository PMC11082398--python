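"""Dataset splitting, model-selection grid, and final model training.

The feature table (one patch-mean spectrum per row) is split once, globally
and at random, into calibration and prediction sets in an 8:2 ratio; the
single split is shared by all four quality targets.  On the calibration
set, every combination of the five spectral pre-treatments with the five
classifiers (logistic regression, RBF support-vector machine, k-nearest
neighbours with k = 5, random forest, Gaussian naive Bayes) is scored by
10-fold cross-validated accuracy, with any stateful preprocessing (the MSC
reference) refitted inside each training fold so no evaluation rows leak
into it.  The best cell per quality wins (ties resolve in fixed method,
then classifier, order), is refitted on the full calibration set, and is
evaluated once on the held-out prediction set.

Binary-only classifiers (logistic regression, SVM) handle the three-class
targets through a one-vs-rest reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from cannaspec.preprocessing import (
    PREPROCESS_METHODS,
    PreprocessState,
    apply_pipeline,
    fit_preprocess,
)
from cannaspec.segmentation import spectrum_columns

__all__ = [
    "CLASSIFIERS",
    "DEFAULT_HYPERPARAMETERS",
    "SelectionGrid",
    "ModelBundle",
    "make_classifier",
    "spectral_matrix",
    "split_dataset",
    "cross_validate_grid",
    "select_best",
    "train_final",
    "predict",
    "predict_scores",
    "boundary_sensitivity_scan",
]

#: Fixed classifier order; also the secondary tie-break order in selection.
CLASSIFIERS = ("LR", "SVM", "KNN", "RF", "GNB")

#: Defaults where the protocol leaves hyperparameters open; k = 5 for KNN
#: is part of the protocol.  All are overridable per call.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "LR": {"C": 1.0, "max_iter": 5000},
    "SVM": {"C": 1.0, "kernel": "rbf"},
    "KNN": {"n_neighbors": 5, "metric": "euclidean", "weights": "uniform"},
    "RF": {"n_estimators": 100, "max_depth": None},
    "GNB": {},
}

N_FOLDS = 10


def make_classifier(name: str, seed: int | None = 0, hyperparameters: Mapping | None = None):
    """Instantiate a classifier by name with the package defaults.

    Logistic regression and SVM are wrapped one-vs-rest; the other three
    are natively multiclass.
    """
    if name not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")
    params = dict(DEFAULT_HYPERPARAMETERS[name])
    if hyperparameters:
        params.update(hyperparameters)
    if name == "LR":
        return OneVsRestClassifier(LogisticRegression(**params))
    if name == "SVM":
        return OneVsRestClassifier(SVC(**params))
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    return GaussianNB(**params)


def spectral_matrix(table: pd.DataFrame) -> np.ndarray:
    """Extract the ``N x B`` reflectance matrix from a spectrum table."""
    cols = [c for c in table.columns if c.startswith("b") and c[1:].isdigit()]
    if not cols:
        raise ValueError("table has no spectral columns (b000, b001, ...)")
    expected = spectrum_columns(len(cols))
    if cols != expected:
        raise ValueError("spectral columns are not contiguous b000..bNNN")
    return table[cols].to_numpy(dtype=float)


def split_dataset(
    table: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One global random calibration/prediction split shared by all targets.

    The prediction-set size is ``ceil(test_fraction * N)`` (4,707 rows at
    the default fraction give a 942-row prediction set).  Rows keep their
    original order within each part; the split is reproducible from the
    seed alone.
    """
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split; got {n}")
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must lie in (0, 1); got {test_fraction}")
    n_test = math.ceil(test_fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return table.iloc[train_idx].reset_index(drop=True), table.iloc[test_idx].reset_index(drop=True)


@dataclass
class SelectionGrid:
    """Mean 10-fold CV accuracies per quality, plus the fold bookkeeping.

    ``accuracies[quality]`` is a preprocessing x classifier DataFrame of
    mean fold accuracies in [0, 1].  ``fold_msc_references[f]`` records the
    MSC reference fitted on fold ``f``'s training rows, kept so leakage is
    auditable after the fact.
    """

    accuracies: dict[str, pd.DataFrame]
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    fold_msc_references: dict[int, np.ndarray] = field(default_factory=dict)


def _check_class_counts(y: np.ndarray, quality: str, n_folds: int) -> None:
    values, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(values, counts):
        if cnt < n_folds:
            raise ValueError(
                f"{quality}: class {cls!r} has only {cnt} calibration rows; "
                f"{n_folds}-fold cross-validation needs at least {n_folds}"
            )


def cross_validate_grid(
    calibration: pd.DataFrame,
    label_columns: Mapping[str, str] | Sequence[str],
    seed: int = 0,
    methods: Sequence[str] = PREPROCESS_METHODS,
    classifiers: Sequence[str] = CLASSIFIERS,
    n_folds: int = N_FOLDS,
    band_spacing_nm: float = 1.0,
    hyperparameters: Mapping[str, Mapping] | None = None,
) -> SelectionGrid:
    """Score every preprocessing x classifier combination per quality.

    ``label_columns`` maps quality name to the column of ``calibration``
    holding its class labels (or is a list of columns named after their
    quality).  Folds are a seeded shuffled K-fold without stratification,
    shared across qualities and combinations; preprocessing state is fitted
    on each fold's training rows only.
    """
    if isinstance(label_columns, Mapping):
        quality_cols = dict(label_columns)
    else:
        quality_cols = {q: q for q in label_columns}
    X = spectral_matrix(calibration)
    labels = {q: calibration[col].to_numpy() for q, col in quality_cols.items()}
    for quality, y in labels.items():
        _check_class_counts(y, quality, n_folds)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr, va) for tr, va in kf.split(X)]

    hp = hyperparameters or {}
    scores = {
        q: pd.DataFrame(0.0, index=list(methods), columns=list(classifiers))
        for q in labels
    }
    msc_refs: dict[int, np.ndarray] = {}
    for fold_id, (tr, va) in enumerate(folds):
        for method in methods:
            state = fit_preprocess(method, X[tr], band_spacing_nm=band_spacing_nm)
            if method == "msc" and state.reference_spectrum is not None:
                msc_refs[fold_id] = state.reference_spectrum
            Xtr = apply_pipeline(method, X[tr], state)
            Xva = apply_pipeline(method, X[va], state)
            for clf_name in classifiers:
                for quality, y in labels.items():
                    clf_q = make_classifier(
                        clf_name, seed=seed, hyperparameters=hp.get(clf_name)
                    )
                    clf_q.fit(Xtr, y[tr])
                    acc = float(np.mean(clf_q.predict(Xva) == y[va]))
                    scores[quality].loc[method, clf_name] += acc
    for quality in scores:
        scores[quality] /= n_folds
    return SelectionGrid(
        accuracies=scores, folds=folds, seed=seed, fold_msc_references=msc_refs
    )


def select_best(
    grid: SelectionGrid,
    methods: Sequence[str] = PREPROCESS_METHODS,
    classifiers: Sequence[str] = CLASSIFIERS,
) -> dict[str, tuple[str, str]]:
    """Arg-max cell per quality; ties break by method, then classifier, order."""
    winners: dict[str, tuple[str, str]] = {}
    for quality, table in grid.accuracies.items():
        best: tuple[str, str] | None = None
        best_acc = -np.inf
        for method in methods:
            for clf in classifiers:
                acc = float(table.loc[method, clf])
                if acc > best_acc:
                    best_acc = acc
                    best = (method, clf)
        assert best is not None
        winners[quality] = best
    return winners


@dataclass
class ModelBundle:
    """A trained (preprocessing, classifier) pair for one quality target."""

    quality: str
    method: str
    classifier_name: str
    state: PreprocessState
    classifier: object
    class_order: tuple[str, ...]
    seed: int
    n_bands: int
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        bundle = joblib.load(Path(path))
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def train_final(
    calibration: pd.DataFrame,
    quality: str,
    combo: tuple[str, str],
    label_column: str | None = None,
    seed: int = 0,
    band_spacing_nm: float = 1.0,
    class_order: Sequence[str] | None = None,
    hyperparameters: Mapping | None = None,
) -> ModelBundle:
    """Refit the winning combination on the full calibration set."""
    method, clf_name = combo
    X = spectral_matrix(calibration)
    y = calibration[label_column or quality].to_numpy()
    state = fit_preprocess(method, X, band_spacing_nm=band_spacing_nm)
    Xp = apply_pipeline(method, X, state)
    clf = make_classifier(clf_name, seed=seed, hyperparameters=hyperparameters)
    clf.fit(Xp, y)
    observed = tuple(clf.classes_)
    if class_order is None:
        order = observed
    else:
        order = tuple(c for c in class_order if c in observed)
        if set(order) != set(observed):
            raise ValueError("class_order does not cover the training classes")
    return ModelBundle(
        quality=quality,
        method=method,
        classifier_name=clf_name,
        state=state,
        classifier=clf,
        class_order=order,
        seed=seed,
        n_bands=X.shape[1],
    )


def _reorder_columns(
    values: np.ndarray, from_order: Sequence[str], to_order: Sequence[str]
) -> np.ndarray:
    idx = [list(from_order).index(c) for c in to_order]
    return values[:, idx]


def predict_scores(bundle: ModelBundle, spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-class scores in ``bundle.class_order``.

    Scores are probabilities where the classifier defines them (normalized
    to sum to one across classes) and decision-function margins otherwise
    (RBF SVM without probability calibration).
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim == 1:
        X = X[np.newaxis, :]
    if X.shape[1] != bundle.n_bands:
        raise ValueError(
            f"spectra have {X.shape[1]} bands; model was trained on {bundle.n_bands}"
        )
    Xp = apply_pipeline(bundle.method, X, bundle.state)
    clf = bundle.classifier
    labels = np.asarray(clf.predict(Xp))
    if hasattr(clf, "predict_proba"):
        scores = np.asarray(clf.predict_proba(Xp), dtype=float)
        row_sums = scores.sum(axis=1, keepdims=True)
        row_sums[row_sums == 0] = 1.0
        scores = scores / row_sums
    else:
        scores = np.asarray(clf.decision_function(Xp), dtype=float)
        if scores.ndim == 1:  # binary: single margin column
            scores = np.column_stack([-scores, scores])
    scores = _reorder_columns(scores, tuple(clf.classes_), bundle.class_order)
    return labels, scores


def predict(bundle: ModelBundle, spectra: np.ndarray) -> np.ndarray:
    """Predicted class labels for raw (untreated) spectra."""
    labels, _ = predict_scores(bundle, spectra)
    return labels


def boundary_sensitivity_scan(
    calibration: pd.DataFrame,
    quantity_column: str,
    candidate_boundaries: Sequence[Sequence[float]],
    seed: int = 0,
    n_folds: int = N_FOLDS,
) -> pd.DataFrame:
    """LR-on-raw CV accuracy for alternative class-boundary sets.

    Each candidate is a sorted list of interior edges partitioning
    (0, 100] into upper-inclusive intervals; rows are relabelled by
    interval membership and scored with 10-fold cross-validated
    logistic-regression accuracy on the raw spectra.  Candidates that
    leave a class too small for the fold count are recorded as skipped.
    Returns one row per candidate with columns ``boundaries``,
    ``accuracy``, ``skipped``, ``note``.
    """
    X = spectral_matrix(calibration)
    q = calibration[quantity_column].to_numpy(dtype=float)
    if np.any(~((q > 0) & (q <= 100))):
        raise ValueError(f"{quantity_column} values must lie in (0, 100]")
    records = []
    for edges in candidate_boundaries:
        edges = sorted(float(e) for e in edges)
        if any(not 0 < e < 100 for e in edges):
            records.append(
                {"boundaries": tuple(edges), "accuracy": np.nan, "skipped": True,
                 "note": "edges outside (0, 100)"}
            )
            continue
        y = np.digitize(q, edges, right=True)
        _, counts = np.unique(y, return_counts=True)
        if len(counts) < len(edges) + 1 or counts.min() < n_folds:
            records.append(
                {"boundaries": tuple(edges), "accuracy": np.nan, "skipped": True,
                 "note": "a class is empty or smaller than the fold count"}
            )
            continue
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        accs = []
        for tr, va in kf.split(X):
            clf = make_classifier("LR", seed=seed)
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[va]) == y[va])))
        records.append(
            {"boundaries": tuple(edges), "accuracy": float(np.mean(accs)),
             "skipped": False, "note": ""}
        )
    return pd.DataFrame(records, columns=["boundaries", "accuracy", "skipped", "note"])
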