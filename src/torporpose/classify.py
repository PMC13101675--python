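"""Leave-one-animal-out torpor classification with a linear model.

Within each fold (one animal held out), the training bouts are class-balanced
by random undersampling of the majority class, standardized, projected onto
the smallest set of principal components reaching >= 90% cumulative explained
variance, and fed to an L2-regularized logistic regression (C = 1.0).  The
held-out animal's bouts are scored through that fold's transforms, so every
bout receives exactly one torpor probability from a model that never saw its
animal.  Torpor is the positive class throughout; ties at the 0.5 decision
threshold go to torpor.

PC-space coefficients are back-projected to the standardized 12-feature space
through the fold's loading matrix; mean absolute back-projected weights across
folds attribute the decision boundary to named posture features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cluster import PcaModel, StandardizationParams, pca_fit_project, standardize
from .features import FEATURE_NAMES

POSITIVE_CLASS = "torpor"


@dataclass
class FoldModel:
    """Transforms and classifier fitted on one training fold."""

    held_out_animal: str
    standardization: StandardizationParams
    pca: PcaModel
    coef: np.ndarray  # (m,) PC-space logistic coefficients
    intercept: float
    C: float

    @property
    def n_components(self) -> int:
        return self.pca.n_components

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Torpor probability for raw 12-feature bout vectors."""
        Z = self.standardization.transform(X)
        scores = self.pca.project(Z)
        from scipy.special import expit

        return expit(scores @ self.coef + self.intercept)


def _n_components_for_variance(standardized: np.ndarray, target: float) -> int:
    _, s, _ = np.linalg.svd(
        standardized - standardized.mean(axis=0), full_matrices=False
    )
    var = s**2
    ratio = np.cumsum(var) / var.sum()
    return int(np.searchsorted(ratio, target - 1e-12) + 1)


def _undersample(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices balancing the two classes by undersampling the majority."""
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    n = min(len(pos), len(neg))
    if n < 2:
        raise ValueError("a class has fewer than 2 bouts after undersampling")
    keep_pos = rng.choice(pos, size=n, replace=False) if len(pos) > n else pos
    keep_neg = rng.choice(neg, size=n, replace=False) if len(neg) > n else neg
    return np.sort(np.concatenate([keep_pos, keep_neg]))


def _fit_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    held_out: str,
    C: float,
    variance_target: float,
    rng: np.random.Generator,
    undersample: bool,
) -> FoldModel:
    if undersample:
        idx = _undersample(y_train, rng)
        X_train, y_train = X_train[idx], y_train[idx]
    Z, std_params = standardize(X_train)
    m = _n_components_for_variance(Z, variance_target)
    pca_model, scores = pca_fit_project(Z, m)
    clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-6, max_iter=1000)
    clf.fit(scores, y_train.astype(int))
    return FoldModel(
        held_out_animal=held_out,
        standardization=std_params,
        pca=pca_model,
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        C=C,
    )


def _validate_inputs(
    X: np.ndarray, labels: np.ndarray, animals: np.ndarray
) -> np.ndarray:
    if not (len(X) == len(labels) == len(animals)):
        raise ValueError("features, labels and animals must align")
    y = labels == POSITIVE_CLASS
    for a in np.unique(animals):
        if len(np.unique(labels[animals == a])) > 1:
            raise ValueError(f"animal {a!r} has bouts in both classes")
    if len(np.unique(animals[y])) < 2 or len(np.unique(animals[~y])) < 2:
        raise ValueError("need at least 2 animals per class")
    return y


def loocv_classify(
    bout_features: np.ndarray,
    labels: np.ndarray,
    animals: np.ndarray,
    C: float = 1.0,
    variance_target: float = 0.90,
    seed: int = 0,
    undersample: bool = True,
) -> tuple[list[FoldModel], pd.DataFrame]:
    """Leave-one-animal-out cross-validated torpor classification.

    Parameters
    ----------
    bout_features : (n_bouts, 12) bout-averaged posture features.
    labels : per-bout condition labels; ``"torpor"`` is the positive class.
    animals : per-bout animal ids; one fold per unique id.

    Returns
    -------
    fold_models : one fitted :class:`FoldModel` per animal.
    result : DataFrame with columns ``probability``, ``predicted``, ``true``,
        ``animal``, ``fold`` — one row per bout, scored by the fold holding
        out its animal.
    """
    X = np.asarray(bout_features, dtype=float)
    labels = np.asarray(labels)
    animals = np.asarray(animals)
    y = _validate_inputs(X, labels, animals)

    fold_animals = list(dict.fromkeys(animals.tolist()))  # stable order
    root = np.random.default_rng(seed)
    fold_rngs = root.spawn(len(fold_animals))

    folds: list[FoldModel] = []
    prob = np.empty(len(X))
    fold_id = np.empty(len(X), dtype=int)
    for f, animal in enumerate(fold_animals):
        test = animals == animal
        model = _fit_fold(
            X[~test], y[~test], animal, C, variance_target, fold_rngs[f], undersample
        )
        folds.append(model)
        prob[test] = model.predict_proba(X[test])
        fold_id[test] = f

    result = pd.DataFrame(
        {
            "probability": prob,
            "predicted": np.where(prob >= 0.5, POSITIVE_CLASS, "comparison"),
            "true": np.where(y, POSITIVE_CLASS, "comparison"),
            "animal": animals,
            "fold": fold_id,
        }
    )
    return folds, result


def roc_auc(result: pd.DataFrame) -> dict:
    """ROC curve (threshold sweep over unique probabilities) and trapezoidal
    AUROC; tied scores are handled by the sweep itself, matching the
    Mann-Whitney pairwise definition."""
    y = (result["true"] == POSITIVE_CLASS).to_numpy()
    p = result["probability"].to_numpy()
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, p)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
        "auroc": float(_sk_auc(fpr, tpr)),
    }


def confusion_metrics(result: pd.DataFrame, threshold: float = 0.5) -> dict:
    """Confusion matrix and standard rates with torpor as the positive class.

    Probability exactly at the threshold predicts torpor (>= convention).
    """
    y = (result["true"] == POSITIVE_CLASS).to_numpy()
    pred = result["probability"].to_numpy() >= threshold
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    n = tp + fn + tn + fp

    def _rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "accuracy": _rate(tp + tn, n),
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
        "precision": _rate(tp, tp + fp),
        "npv": _rate(tn, tn + fn),
    }


def shuffled_control(
    bout_features: np.ndarray,
    labels: np.ndarray,
    animals: np.ndarray,
    n_shuffles: int = 100,
    C: float = 1.0,
    variance_target: float = 0.90,
    seed: int = 0,
) -> np.ndarray:
    """Chance-level reference: labels permuted within each training fold.

    For each shuffle the full per-fold pipeline (undersample, standardize,
    PCA, logistic fit) is re-run on permuted training labels — with a fresh
    undersampling draw — and the held-out bouts are scored against their
    *true* labels.  Returns ``n_shuffles`` fold-averaged accuracies.
    """
    X = np.asarray(bout_features, dtype=float)
    labels = np.asarray(labels)
    animals = np.asarray(animals)
    y = _validate_inputs(X, labels, animals)
    fold_animals = list(dict.fromkeys(animals.tolist()))
    root = np.random.default_rng(seed)

    accuracies = np.empty(n_shuffles)
    for s in range(n_shuffles):
        fold_acc = []
        for animal in fold_animals:
            test = animals == animal
            y_train = y[~test].copy()
            root.shuffle(y_train)
            model = _fit_fold(
                X[~test], y_train, animal, C, variance_target, root, undersample=True
            )
            pred = model.predict_proba(X[test]) >= 0.5
            fold_acc.append(float(np.mean(pred == y[test])))
        accuracies[s] = np.mean(fold_acc)
    return accuracies


def backproject_weights(fold_models: list[FoldModel]) -> pd.Series:
    """Mean absolute standardized feature weights across folds.

    Each fold's PC-space coefficients are mapped to the standardized
    12-feature space through that fold's loading matrix; absolute values are
    averaged across folds.  Larger values mark features that consistently
    drive the decision boundary.
    """
    if not fold_models:
        raise ValueError("need at least one fold model")
    weights = np.mean(
        [np.abs(m.pca.loadings @ m.coef) for m in fold_models], axis=0
    )
    names = (
        FEATURE_NAMES
        if len(weights) == len(FEATURE_NAMES)
        else [f"feature_{i}" for i in range(len(weights))]
    )
    return pd.Series(weights, index=list(names), name="mean_abs_weight")
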