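"""Landmark-RMSD featurization.

Each trajectory frame is represented by its vector of RMSD values to a
fixed set of reference structures (landmarks).  Landmarks are chosen by
k-medoids clustering of pairwise RMSD over a subsampled frame pool, so
every landmark is an actual input frame, never an average.  The default of
500 landmarks matches the emulated study protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .trajio import TrajectoryEnsemble

__all__ = [
    "LandmarkSet",
    "FeatureMatrix",
    "rmsd",
    "select_landmarks",
    "featurize_ensemble",
]


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _batch_rmsd(frames: np.ndarray, ref: np.ndarray, superpose: bool) -> np.ndarray:
    """RMSD of many frames (m, n, 3) against one reference (n, 3).

    With ``superpose`` the optimal rigid-body superposition (Kabsch, via a
    batched 3x3 SVD with the proper-rotation determinant correction) is
    applied first.
    """
    frames = np.asarray(frames, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n = ref.shape[0]
    if not superpose:
        diff = frames - ref[None]
        return np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))
    a = frames - frames.mean(axis=1, keepdims=True)
    b = ref - ref.mean(axis=0)
    # Kabsch: H = bᵀa per frame, R = U diag(1,1,d) Vᵀ with the determinant
    # correction restricting to proper rotations; the RMSD is then taken on
    # the explicitly rotated difference, which stays accurate near zero
    # (the Ga + Gb − 2·trace shortcut cancels catastrophically there).
    h = np.einsum("np,mnq->mpq", b, a)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", u, vt)))
    u[:, :, 2] *= d[:, None]
    rot = np.einsum("mij,mjk->mik", u, vt)
    diff = a - np.einsum("ni,mik->mnk", b, rot)
    return np.sqrt(np.sum(diff * diff, axis=(1, 2)) / n)


def rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    atom_indices: np.ndarray | None = None,
    superpose: bool = True,
) -> float:
    """Root-mean-square deviation between two frames, in Å.

    With ``superpose`` the frames are optimally superposed (Kabsch) on
    ``atom_indices`` first; at least 3 atoms are then required.  Without it
    the raw coordinate RMSD is returned.  Symmetric in its arguments.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if atom_indices is not None:
        a = a[np.asarray(atom_indices, dtype=np.intp)]
        b = b[np.asarray(atom_indices, dtype=np.intp)]
    if a.shape != b.shape:
        raise ValidationError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if superpose and a.shape[0] < 3:
        raise ValidationError("superposition requires at least 3 atoms")
    return float(_batch_rmsd(a[None], b, superpose)[0])


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Medoid frames used as RMSD references.

    ``coords`` holds the selected atoms of each landmark frame,
    ``source_frames`` the (trajectory index, frame index) provenance, and
    ``atom_indices`` the selection the RMSD is computed over.
    """

    coords: np.ndarray                 # (n_landmarks, n_sel_atoms, 3)
    source_frames: list[tuple[int, int]]
    atom_indices: np.ndarray
    superpose: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 2:
            raise ValidationError("need >= 2 landmark frames of shape (n_atoms, 3)")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


def _pairwise_rmsd(coords: np.ndarray, superpose: bool) -> np.ndarray:
    m = coords.shape[0]
    dist = np.zeros((m, m))
    for i in range(m):
        dist[i, i + 1:] = _batch_rmsd(coords[i + 1:], coords[i], superpose)
    return dist + dist.T


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator,
              n_init: int = 5, max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on a precomputed distance matrix.

    k-medoids++ seeding followed by Voronoi iteration (assign, then move
    each medoid to the member minimising total intra-cluster distance);
    best of ``n_init`` restarts by total cost.  Ties break to the lowest
    frame index.  Returns sorted medoid indices.
    """
    m = dist.shape[0]
    if k == m:
        return np.arange(m)
    best_cost, best = np.inf, None
    for _ in range(n_init):
        medoids = [int(rng.integers(m))]
        d_near = dist[medoids[0]].copy()
        while len(medoids) < k:
            p = d_near**2
            tot = p.sum()
            if tot <= 0:
                remaining = np.setdiff1d(np.arange(m), medoids)
                medoids.extend(remaining[: k - len(medoids)].tolist())
                break
            nxt = int(rng.choice(m, p=p / tot))
            if nxt not in medoids:
                medoids.append(nxt)
                d_near = np.minimum(d_near, dist[nxt])
        medoids = np.array(sorted(medoids[:k]))
        for _ in range(max_iter):
            labels = np.argmin(dist[medoids], axis=0)
            new = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    continue
                intra = dist[np.ix_(members, members)].sum(axis=1)
                new[c] = members[int(np.argmin(intra))]
            new = np.sort(new)
            if np.array_equal(new, medoids):
                break
            medoids = new
        cost = dist[medoids].min(axis=0).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, medoids
    return best


def select_landmarks(
    ensemble: TrajectoryEnsemble,
    atom_indices: np.ndarray | None = None,
    n_landmarks: int = 500,
    max_frames_for_medoid: int = 10_000,
    seed: int = 0,
    superpose: bool = True,
) -> LandmarkSet:
    """Choose landmark frames by k-medoids on the RMSD metric.

    Medoid search runs on a uniformly subsampled pool of at most
    ``max_frames_for_medoid`` frames; all frames are later featurized
    against the chosen medoids.  Reproducible for a fixed seed.
    """
    xyz, traj_idx, frame_idx = ensemble.stacked()
    if atom_indices is None:
        atom_indices = np.arange(ensemble.n_atoms, dtype=np.intp)
    else:
        atom_indices = np.asarray(atom_indices, dtype=np.intp)
    sel = xyz[:, atom_indices]
    total = sel.shape[0]
    if n_landmarks < 2:
        raise ValidationError("n_landmarks must be >= 2")
    if n_landmarks > total:
        raise ValidationError(
            f"n_landmarks ({n_landmarks}) exceeds available frames ({total})"
        )
    if superpose and atom_indices.size < 3:
        superpose = False   # plain coordinate RMSD for point-like systems
    rng = np.random.default_rng(seed)
    if total > max_frames_for_medoid:
        pool = np.sort(rng.choice(total, size=max_frames_for_medoid, replace=False))
    else:
        pool = np.arange(total)
    if n_landmarks > pool.size:
        raise ValidationError(
            f"n_landmarks ({n_landmarks}) exceeds the medoid pool ({pool.size})"
        )
    dist = _pairwise_rmsd(sel[pool], superpose)
    medoid_pool_idx = _kmedoids(dist, n_landmarks, rng)
    chosen = pool[medoid_pool_idx]
    return LandmarkSet(
        coords=sel[chosen],
        source_frames=[(int(traj_idx[i]), int(frame_idx[i])) for i in chosen],
        atom_indices=atom_indices,
        superpose=superpose,
    )


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per-frame landmark-RMSD vectors with trajectory bookkeeping.

    ``values[f, j]`` is the RMSD (Å) of frame ``f`` to landmark ``j``;
    ``traj_idx``/``frame_idx`` map stacked rows back to trajectories.
    """

    values: np.ndarray
    traj_idx: np.ndarray
    frame_idx: np.ndarray
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("RMSD features must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def split_by_trajectory(self) -> list[np.ndarray]:
        out = []
        for t in np.unique(self.traj_idx):
            out.append(self.values[self.traj_idx == t])
        return out


def featurize_ensemble(
    ensemble: TrajectoryEnsemble,
    landmarks: LandmarkSet,
    superpose: bool | None = None,
) -> FeatureMatrix:
    """RMSD of every frame to every landmark; one batched pass per landmark."""
    if superpose is None:
        superpose = landmarks.superpose
    xyz, traj_idx, frame_idx = ensemble.stacked()
    sel = xyz[:, landmarks.atom_indices]
    if sel.shape[1] != landmarks.coords.shape[1]:
        raise ValidationError(
            f"selection has {sel.shape[1]} atoms, landmarks have "
            f"{landmarks.coords.shape[1]}"
        )
    if superpose and sel.shape[1] < 3:
        raise ValidationError("superposition requires at least 3 atoms")
    values = np.empty((sel.shape[0], landmarks.n_landmarks))
    for j in range(landmarks.n_landmarks):
        values[:, j] = _batch_rmsd(sel, landmarks.coords[j], superpose)
    return FeatureMatrix(
        values=values, traj_idx=traj_idx, frame_idx=frame_idx, landmarks=landmarks
    )
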