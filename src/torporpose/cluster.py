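"""Standardization, PCA projection and GMM clustering of bout-averaged postures.

Bout-mean 12-feature vectors are z-scored across bouts, projected onto
principal components, and clustered with a 4-component full-covariance
Gaussian mixture.  Four raw clusters typically resolve into right-side lying,
left-side lying, curled-up, and forward-facing postures; the two lying
clusters are mirror images of the same posture and are merged, leaving three
semantic labels.  Annotation is user input (in the original workflow it was
done by inspecting video frames); :func:`suggest_annotation` offers a
geometry-based starting point but never overrides the user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .features import FEATURE_NAMES

MERGED_LABELS = ("lying", "curled_up", "forward_facing")


@dataclass
class StandardizationParams:
    mean: np.ndarray  # (n_features,)
    std: np.ndarray  # (n_features,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.std

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.std + self.mean


@dataclass
class PcaModel:
    """PCA loadings and explained variance, sign-fixed for determinism."""

    loadings: np.ndarray  # (n_features, m); columns orthonormal
    explained_variance_ratio: np.ndarray  # (m,), non-increasing
    mean: np.ndarray  # (n_features,) training mean removed before projection

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.loadings

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, float) @ self.loadings.T + self.mean


@dataclass
class ClusterAssignment:
    raw_id: np.ndarray  # (n_bouts,) int in 0..k-1
    merged_label: np.ndarray | None = None  # (n_bouts,) str after annotation
    annotation: dict[int, str] | None = None

    @property
    def n_bouts(self) -> int:
        return len(self.raw_id)


def standardize(features: np.ndarray) -> tuple[np.ndarray, StandardizationParams]:
    """Z-score each feature across bouts (population SD, as in PCA pipelines)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D matrix with at least 2 bouts")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if np.any(std == 0):
        j = int(np.argmax(std == 0))
        name = FEATURE_NAMES[j] if X.shape[1] == len(FEATURE_NAMES) else f"column {j}"
        raise ValueError(f"constant feature {name!r}: cannot standardize")
    params = StandardizationParams(mean=mean, std=std)
    return params.transform(X), params


def pca_fit_project(
    standardized: np.ndarray, n_components: int
) -> tuple[PcaModel, np.ndarray]:
    """Fit PCA and project; component signs fixed so the largest-magnitude
    loading entry of each component is positive."""
    X = np.asarray(standardized, dtype=float)
    eff_rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > eff_rank:
        raise ValueError(
            f"requested {n_components} components but data rank is {eff_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # (p, m)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    model = PcaModel(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
    )
    return model, scores


def gmm_cluster(
    scores: np.ndarray,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    reg_covar: float = 1e-6,
) -> tuple[ClusterAssignment, GaussianMixture]:
    """Fit a full-covariance k-component Gaussian mixture; hard-assign bouts
    by maximum posterior responsibility."""
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < 5 * k:
        raise ValueError(f"need at least {5 * k} bouts to fit a {k}-component GMM")
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        reg_covar=reg_covar,
        random_state=seed,
        max_iter=500,
    )
    gmm.fit(X)
    if not gmm.converged_:
        raise RuntimeError(
            "EM did not converge; a degenerate (collapsing) component is likely — "
            f"try raising reg_covar above {reg_covar:g}"
        )
    return ClusterAssignment(raw_id=gmm.predict(X)), gmm


def annotate_and_merge(
    assignment: ClusterAssignment, annotation: dict[int, str]
) -> ClusterAssignment:
    """Attach semantic labels and merge the two lying clusters into one.

    ``annotation`` maps every raw cluster id to one of ``lying``,
    ``curled_up`` or ``forward_facing``; exactly two ids must map to lying
    (the left/right mirror pair).
    """
    raw_ids = set(np.unique(assignment.raw_id).tolist())
    missing = raw_ids - set(annotation)
    if missing:
        raise ValueError(f"annotation map missing raw cluster id(s) {sorted(missing)}")
    bad = {v for v in annotation.values() if v not in MERGED_LABELS}
    if bad:
        raise ValueError(f"unknown semantic label(s) {sorted(bad)}")
    n_lying = sum(1 for v in annotation.values() if v == "lying")
    if n_lying != 2:
        raise ValueError(f"exactly two raw ids must map to 'lying', got {n_lying}")
    merged = np.array([annotation[int(i)] for i in assignment.raw_id])
    return ClusterAssignment(
        raw_id=assignment.raw_id, merged_label=merged, annotation=dict(annotation)
    )


def suggest_annotation(
    bout_features: np.ndarray, assignment: ClusterAssignment
) -> dict[int, str]:
    """Heuristic raw-cluster labels from cluster-mean geometry.

    Lying clusters show a large shared lateral (x) offset of ears and hips;
    of the remaining two clusters, the one with the higher mean nose movement
    is called forward-facing and the other curled-up.  Intended as a starting
    point for manual annotation against video frames.
    """
    X = np.asarray(bout_features, dtype=float)
    ids = np.unique(assignment.raw_id)
    if len(ids) != 4:
        raise ValueError("heuristic expects exactly 4 raw clusters")
    name = {n: i for i, n in enumerate(FEATURE_NAMES)}
    lateral, nose_move = {}, {}
    for cid in ids:
        mu = X[assignment.raw_id == cid].mean(axis=0)
        lateral[int(cid)] = abs(
            mu[name["right_ear_x"]] + mu[name["left_ear_x"]]
        ) + abs(mu[name["right_hip_x"]] + mu[name["left_hip_x"]])
        nose_move[int(cid)] = mu[name["nose_movement"]]
    by_lateral = sorted(lateral, key=lateral.get, reverse=True)
    lying = by_lateral[:2]
    rest = by_lateral[2:]
    forward = max(rest, key=lambda c: nose_move[c])
    curled = next(c for c in rest if c != forward)
    out = {c: "lying" for c in lying}
    out[curled] = "curled_up"
    out[forward] = "forward_facing"
    return out


def composition_summary(
    assignment: ClusterAssignment, metadata: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Cluster/condition composition tables and per-animal label sequences.

    ``metadata`` must have one row per bout with columns ``condition``,
    ``animal`` and ``start_time``.  Returns per-cluster condition proportions
    (rows sum to 1), per-condition cluster proportions (rows sum to 1), and a
    time-ordered long table of labels per animal for raster displays.
    """
    if len(metadata) != assignment.n_bouts:
        raise ValueError("metadata rows must align with bouts")
    labels = (
        assignment.merged_label
        if assignment.merged_label is not None
        else assignment.raw_id.astype(str)
    )
    table = metadata.copy()
    table["label"] = labels
    counts = table.groupby(["label", "condition"]).size().unstack(fill_value=0)
    by_cluster = counts.div(counts.sum(axis=1), axis=0)
    by_condition = counts.T.div(counts.sum(axis=0), axis=0)
    raster = table.sort_values(["animal", "start_time"])[
        ["animal", "start_time", "condition", "label"]
    ].reset_index(drop=True)
    return {
        "condition_within_cluster": by_cluster,
        "cluster_within_condition": by_condition,
        "raster": raster,
    }
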