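"""High-level pipelines chaining segmentation, features, clustering, classification.

These functions wire the per-module operations into the two standard analyses:

* torpor vs sleep — 10-s immobility bins, >= 4-bin ("40-s rule") bouts from
  both conditions, bout-averaged 12-feature vectors, GMM posture clustering,
  then leave-one-animal-out classification restricted to the curled-up
  cluster;
* torpor vs cold — condition-specific minimum run lengths (>= 4 bins for
  torpor, >= 1 bin for cold) and classification on all immobile bouts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import backproject_weights, confusion_metrics, loocv_classify, roc_auc
from .cluster import (
    annotate_and_merge,
    gmm_cluster,
    pca_fit_project,
    standardize,
    suggest_annotation,
)
from .features import bin_features, bout_average_features
from .segmentation import extract_bouts, immobile_bins_10s
from .simulate import SyntheticCohort

#: minimum consecutive immobile 10-s bins per condition (the "40-s rule",
#: relaxed to single bins for transient cold-exposure postures)
DEFAULT_MIN_BINS = {"torpor": 4, "sleep": 4, "cold": 1, "amp": 4}


def extract_condition_bouts(
    cohort: SyntheticCohort,
    conditions: tuple[str, ...] | None = None,
    min_bins: dict[str, int] | None = None,
    bin_duration: float = 10.0,
    displacement_cutoff: float = 50.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Immobility-defined bouts and their bout-averaged posture features.

    Returns the (n_bouts, 12) feature matrix and a metadata DataFrame with
    one row per bout (``animal``, ``condition``, ``start_time``,
    ``end_time``, ``n_bins``).
    """
    min_bins = {**DEFAULT_MIN_BINS, **(min_bins or {})}
    rows = []
    mats = []
    for animal in cohort:
        if conditions is not None and animal.condition not in conditions:
            continue
        labels = immobile_bins_10s(
            animal.track, bin_duration, displacement_cutoff
        )
        bouts = extract_bouts(
            labels,
            min_consecutive=min_bins[animal.condition],
            bin_duration=bin_duration,
            animal_id=animal.animal_id,
            condition=animal.condition,
        )
        if len(bouts) == 0:
            continue
        feats, _ = bin_features(animal.track, bin_duration)
        mats.append(bout_average_features(bouts, feats))
        for bout in bouts:
            rows.append(
                {
                    "animal": animal.animal_id,
                    "condition": animal.condition,
                    "start_time": bout.start_time,
                    "end_time": bout.end_time,
                    "n_bins": bout.n_bins,
                }
            )
    if not mats:
        raise ValueError("no bouts extracted from the cohort")
    return np.vstack(mats), pd.DataFrame(rows)


def cluster_bouts(
    bout_features: np.ndarray,
    seed: int = 0,
    k: int = 4,
    n_pcs: int = 2,
    annotation: dict[int, str] | None = None,
):
    """Standardize -> PCA -> GMM -> annotate/merge posture clusters.

    When no annotation map is supplied the geometry heuristic of
    :func:`torporpose.cluster.suggest_annotation` is used.  Returns the merged
    :class:`~torporpose.cluster.ClusterAssignment` plus the fitted models.
    """
    Z, std_params = standardize(bout_features)
    pca_model, scores = pca_fit_project(Z, n_pcs)
    raw, gmm = gmm_cluster(scores, k=k, seed=seed)
    if annotation is None:
        annotation = suggest_annotation(bout_features, raw)
    merged = annotate_and_merge(raw, annotation)
    return merged, {"standardization": std_params, "pca": pca_model, "gmm": gmm}


def classify_torpor_vs_sleep(
    cohort: SyntheticCohort, seed: int = 0, n_shuffles: int = 0
) -> dict:
    """Full torpor-vs-sleep analysis restricted to the curled-up cluster."""
    X, meta = extract_condition_bouts(cohort, conditions=("torpor", "sleep"))
    assignment, models = cluster_bouts(X, seed=seed)
    mask = assignment.merged_label == "curled_up"
    if mask.sum() < 10:
        raise ValueError("too few curled-up bouts to classify")
    return _classify(
        X[mask], meta[mask].reset_index(drop=True), seed, n_shuffles,
        extra={"assignment": assignment, "cluster_models": models, "curled_mask": mask},
    )


def classify_torpor_vs_cold(
    cohort: SyntheticCohort, seed: int = 0, n_shuffles: int = 0
) -> dict:
    """Torpor-vs-cold analysis on all immobile bouts (condition-specific
    minimum run lengths)."""
    X, meta = extract_condition_bouts(cohort, conditions=("torpor", "cold"))
    return _classify(X, meta, seed, n_shuffles, extra={})


def _classify(X, meta, seed, n_shuffles, extra) -> dict:
    from .classify import shuffled_control

    folds, result = loocv_classify(
        X, meta["condition"].to_numpy(), meta["animal"].to_numpy(), seed=seed
    )
    out = {
        "folds": folds,
        "result": result,
        "roc": roc_auc(result),
        "metrics": confusion_metrics(result),
        "weights": backproject_weights(folds),
        "features": X,
        "meta": meta,
        **extra,
    }
    if n_shuffles:
        out["shuffled_accuracy"] = shuffled_control(
            X,
            meta["condition"].to_numpy(),
            meta["animal"].to_numpy(),
            n_shuffles=n_shuffles,
            seed=seed,
        )
    return out
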