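"""PCA compression of feature vectors and k-means microstate clustering.

The pipeline compresses landmark-RMSD feature vectors to 10 principal
components and partitions PC space into 1,000 k-means microstates by
default, matching the emulated study protocol.  PCA and k-means are backed
by scikit-learn; the PCA component signs follow a fixed convention (the
largest-magnitude loading of each component is positive) so results are
deterministic, and k-means distance is unscaled Euclidean in PC space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.decomposition import PCA

from .exceptions import ValidationError
from .featurize import FeatureMatrix

__all__ = [
    "PCAModel",
    "MicrostateAssignment",
    "fit_pca",
    "transform",
    "inverse_transform",
    "cluster_microstates",
]


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray           # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.components.shape[0]), atol=1e-8):
            raise ValidationError("PCA components must be orthonormal")
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or np.any(evr < -1e-12) or evr.sum() > 1 + 1e-8:
            raise ValidationError("explained variance ratios must be non-increasing, in [0,1]")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, features) -> np.ndarray:
        return transform(self, features)

    def inverse_transform(self, pcs: np.ndarray) -> np.ndarray:
        return inverse_transform(self, pcs)


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def fit_pca(features, n_components: int = 10) -> PCAModel:
    """Principal components of the centered data covariance.

    Deterministic up to sign; the sign is fixed so each component's
    largest-magnitude loading is positive.
    """
    x = _as_array(features)
    if n_components > x.shape[1]:
        raise ValidationError(
            f"n_components ({n_components}) exceeds feature dimension ({x.shape[1]})"
        )
    if x.shape[0] <= n_components:
        raise ValidationError("need more frames than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(
        mean=pca.mean_,
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_,
        explained_variance=pca.explained_variance_,
    )


def transform(model: PCAModel, features) -> np.ndarray:
    """Project features onto the principal axes: (x − mean) · componentsᵀ."""
    x = _as_array(features)
    if x.shape[-1] != model.mean.shape[0]:
        raise ValidationError(
            f"feature dimension {x.shape[-1]} != model dimension {model.mean.shape[0]}"
        )
    return (x - model.mean) @ model.components.T


def inverse_transform(model: PCAModel, pcs: np.ndarray) -> np.ndarray:
    pcs = np.asarray(pcs, dtype=float)
    return pcs @ model.components + model.mean


@dataclass
class MicrostateAssignment:
    """k-means microstates in PC space with per-frame labels."""

    centers: np.ndarray              # (k, n_components)
    labels: np.ndarray               # stacked frame labels
    traj_idx: np.ndarray
    frame_idx: np.ndarray
    inertia: float

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.centers.shape[0]:
            raise ValidationError("labels out of range")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def discrete_trajectories(self) -> list[np.ndarray]:
        """Per-trajectory label sequences (frame order preserved)."""
        out = []
        for t in np.unique(self.traj_idx):
            m = self.traj_idx == t
            order = np.argsort(self.frame_idx[m], kind="stable")
            out.append(self.labels[m][order])
        return out


def cluster_microstates(
    pcs: np.ndarray,
    k: int = 1000,
    seed: int = 0,
    n_init: int = 5,
    traj_idx: np.ndarray | None = None,
    frame_idx: np.ndarray | None = None,
    minibatch: bool = False,
) -> MicrostateAssignment:
    """k-means microstates with k-means++ init, best of ``n_init`` restarts.

    Full-batch Lloyd iterations are the default for determinism; mini-batch
    updates are available for very large frame counts.
    """
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim != 2:
        raise ValidationError("pcs must be (n_frames, n_components)")
    if k > pcs.shape[0]:
        raise ValidationError(f"k ({k}) exceeds number of frames ({pcs.shape[0]})")
    cls = MiniBatchKMeans if minibatch else KMeans
    km = cls(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(pcs)
    if traj_idx is None:
        traj_idx = np.zeros(pcs.shape[0], dtype=np.intp)
    if frame_idx is None:
        frame_idx = np.arange(pcs.shape[0], dtype=np.intp)
    return MicrostateAssignment(
        centers=km.cluster_centers_,
        labels=np.asarray(labels, dtype=np.intp),
        traj_idx=np.asarray(traj_idx, dtype=np.intp),
        frame_idx=np.asarray(frame_idx, dtype=np.intp),
        inertia=float(km.inertia_),
    )
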