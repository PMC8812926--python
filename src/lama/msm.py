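"""Markov state model estimation and spectral analysis.

The model is a discrete-state, discrete-lag description of molecular
kinetics: transitions between microstates are counted at a lag time τ,
restricted to the largest strongly connected (ergodic) microstate set, and
normalised into a row-stochastic transition matrix T(τ).  Its spectrum
yields the stationary distribution π (leading left eigenvector), the
implied relaxation timescales t_i = −τ / ln λ_i, and — through −ln of
binned stationary probability — free-energy landscapes on principal
component planes.

The module follows the Model/Results idiom::

    model = MarkovStateModel(dtrajs, lag=10, frame_interval=10.0, time_unit="ps")
    res = model.fit()
    res.transition_matrix, res.stationary_distribution, res.timescales()
    macro = res.pcca(7)                 # metastable coarse-graining
    flux = res.tpt(source, sink)        # transition path theory
    path = res.sample_path(s0, 10_000)  # trajectory reconstruction

Two estimators are provided: plain row normalisation of the count matrix
(the default), and a maximum-likelihood reversible estimator enforcing
detailed balance (required by PCCA+ and TPT, which assume a real spectrum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import LamaError, ValidationError

__all__ = [
    "CountMatrix",
    "MarkovStateModel",
    "MSMResults",
    "ImpliedTimescales",
    "FreeEnergyLandscape",
    "count_transitions",
    "trim_to_ergodic",
    "estimate_T",
    "implied_timescales",
    "project_free_energy",
    "frame_weights",
    "ck_test",
]

_ROW_TOL = 1e-10
_PI_TOL = 1e-8


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    matrix: np.ndarray
    lag_frames: int
    mode: str = "sliding"        # "sliding" | "strided"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0):
            raise ValidationError("transition counts must be non-negative")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> float:
        return float(self.matrix.sum())


def count_transitions(
    dtrajs: Sequence[np.ndarray],
    lag_frames: int,
    mode: str = "sliding",
    n_states: int | None = None,
) -> CountMatrix:
    """Count (s_t, s_{t+lag}) pairs; counting never crosses trajectory ends.

    Sliding mode counts every offset t; strided mode counts t = 0, lag,
    2·lag, … for strictly independent transition samples.
    """
    if lag_frames < 1:
        raise ValidationError("lag_frames must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValidationError(f"unknown counting mode {mode!r}")
    dtrajs = [np.asarray(d, dtype=np.intp) for d in dtrajs]
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs if d.size)) + 1
    C = np.zeros((n_states, n_states))
    any_counted = False
    for d in dtrajs:
        if d.size <= lag_frames:
            continue
        any_counted = True
        if mode == "sliding":
            src, dst = d[:-lag_frames], d[lag_frames:]
        else:
            src, dst = d[:-lag_frames:lag_frames], d[lag_frames::lag_frames]
        np.add.at(C, (src, dst), 1.0)
    if not any_counted:
        raise ValidationError(
            f"no trajectory is longer than the lag ({lag_frames} frames)"
        )
    return CountMatrix(matrix=C, lag_frames=lag_frames, mode=mode)


def trim_to_ergodic(counts: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Restrict to the largest strongly connected component.

    Connectivity is taken on the directed graph with an edge wherever the
    count is positive.  The largest component is the one with the most
    states (ties broken by total counts); the returned index array maps
    active positions back to original microstate ids.
    """
    C = counts.matrix
    n = C.shape[0]
    n_comp, labels = connected_components(
        csr_matrix(C > 0), directed=True, connection="strong"
    )
    best, best_key = None, None
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        key = (members.size, C[np.ix_(members, members)].sum())
        if best_key is None or key > best_key:
            best, best_key = members, key
    if best is None or best.size == 0:
        raise ValidationError("count matrix has no non-empty ergodic component")
    active = np.sort(best)
    trimmed = CountMatrix(
        matrix=C[np.ix_(active, active)],
        lag_frames=counts.lag_frames,
        mode=counts.mode,
    )
    return trimmed, active


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000):
    """Detailed-balance maximum-likelihood estimator via fixed-point iteration.

    Iterates the stationary conditions of the reversible likelihood on the
    symmetric variables x_ij until the transition matrix changes by less
    than ``tol`` in max-abs norm.
    """
    c_sym = C + C.T
    c_row = C.sum(axis=1)
    x = c_sym.copy()
    x_row = x.sum(axis=1)
    T_prev = x / x_row[:, None]
    for _ in range(max_iter):
        denom = (c_row / x_row)[:, None] + (c_row / x_row)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_row = x.sum(axis=1)
        T = x / x_row[:, None]
        if np.max(np.abs(T - T_prev)) < tol:
            break
        T_prev = T
    pi = x_row / x_row.sum()
    return T, pi


def estimate_T(counts: CountMatrix, reversible: bool = False):
    """Transition matrix and stationary distribution from trimmed counts.

    Non-reversible: T_ij = c_ij / Σ_j c_ij with π from the leading left
    eigenvector.  Reversible: maximum-likelihood detailed-balance estimator.
    """
    C = counts.matrix
    row = C.sum(axis=1)
    if np.any(row == 0):
        raise LamaError(
            "count matrix has an empty row; trim_to_ergodic must be applied first"
        )
    if reversible:
        T, pi = _reversible_mle(C)
    else:
        T = C / row[:, None]
        pi = _leading_left_eigvec(T)
    return T, pi


def _leading_left_eigvec(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _spectrum(T: np.ndarray, pi: np.ndarray, reversible_hint: bool):
    """Eigenvalues (|λ|-sorted) and right/left eigenvectors of T.

    When T satisfies detailed balance w.r.t. π the symmetrised matrix
    D^{1/2} T D^{-1/2} is used, guaranteeing a real spectrum.
    """
    def _order(vals):
        # |λ| descending, but the eigenvalue nearest 1 (the stationary
        # process) always comes first — other unit-modulus eigenvalues
        # (periodic or complex pairs) must not displace it
        order = np.argsort(np.abs(vals))[::-1].tolist()
        lead = int(np.argmin(np.abs(vals - 1.0)))
        order.remove(lead)
        return np.array([lead] + order)

    db = np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)) < 1e-10
    if reversible_hint and db and np.all(pi > 0):
        sq = np.sqrt(pi)
        S = (sq[:, None] * T) / sq[None, :]
        S = 0.5 * (S + S.T)
        vals, y = np.linalg.eigh(S)
        order = _order(vals)
        vals = vals[order]
        y = y[:, order]
        right = y / sq[:, None]
        left = y * sq[:, None]
    else:
        vals, right = np.linalg.eig(T)
        order = _order(vals)
        vals = vals[order]
        right = right[:, order]
        # match left eigenvectors to the sorted eigenvalues
        lvals, lvecs = np.linalg.eig(T.T)
        left = np.empty_like(right)
        used = set()
        for k, v in enumerate(vals):
            diffs = np.abs(lvals - v)
            for j in np.argsort(diffs):
                if j not in used:
                    used.add(j)
                    left[:, k] = lvecs[:, j]
                    break
    # normalise the stationary pair
    right[:, 0] = right[:, 0] / right[0, 0] if right[0, 0] != 0 else right[:, 0]
    return vals, right, left


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MarkovStateModel:
    """Markov state model to be estimated from discrete trajectories.

    Parameters
    ----------
    dtrajs
        Per-trajectory integer microstate label sequences.
    lag
        Lag time in frames at which transitions are counted.
    frame_interval, time_unit
        Physical time per frame and its unit label; the model's lag time is
        ``lag * frame_interval``.
    reversible
        Enforce detailed balance (maximum-likelihood reversible estimator).
        Required for PCCA+ and TPT downstream.
    count_mode
        "sliding" (default) or "strided".
    """

    def __init__(
        self,
        dtrajs: Sequence[np.ndarray],
        lag: int,
        frame_interval: float = 1.0,
        time_unit: str = "steps",
        reversible: bool = False,
        count_mode: str = "sliding",
        n_states: int | None = None,
    ):
        self.dtrajs = [np.asarray(d, dtype=np.intp) for d in dtrajs]
        self.lag = int(lag)
        self.frame_interval = float(frame_interval)
        self.time_unit = time_unit
        self.reversible = reversible
        self.count_mode = count_mode
        self.n_states = n_states

    def fit(self) -> "MSMResults":
        counts_full = count_transitions(
            self.dtrajs, self.lag, self.count_mode, self.n_states
        )
        counts_active, active = trim_to_ergodic(counts_full)
        T, pi = estimate_T(counts_active, reversible=self.reversible)
        return MSMResults(
            transition_matrix=T,
            stationary_distribution=pi,
            active_set=active,
            counts_full=counts_full,
            counts_active=counts_active,
            lag_frames=self.lag,
            lag_time=self.lag * self.frame_interval,
            time_unit=self.time_unit,
            reversible=self.reversible,
            model=self,
        )


@dataclass
class MSMResults:
    """Estimated MSM: transition matrix on the active set, spectrum, π.

    Invariants checked on construction: rows of T sum to 1 (1e-10), the
    leading eigenvalue is 1 (1e-8), the spectral radius is 1, and π is a
    probability vector with πT = π (1e-8).
    """

    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    active_set: np.ndarray
    lag_time: float
    lag_frames: int = 1
    time_unit: str = "steps"
    reversible: bool = False
    counts_full: CountMatrix | None = None
    counts_active: CountMatrix | None = None
    model: MarkovStateModel | None = None
    eigenvalues: np.ndarray = field(init=False)
    right_eigenvectors: np.ndarray = field(init=False)
    left_eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.stationary_distribution, dtype=float)
        self.transition_matrix = T
        self.stationary_distribution = pi
        self.active_set = np.asarray(self.active_set, dtype=np.intp)
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > _ROW_TOL:
            raise LamaError("transition matrix rows do not sum to 1")
        if np.any(pi < -_PI_TOL) or abs(pi.sum() - 1.0) > _PI_TOL:
            raise LamaError("stationary distribution is not a probability vector")
        if np.max(np.abs(pi @ T - pi)) > _PI_TOL:
            raise LamaError("stationary distribution does not satisfy πT = π")
        vals, right, left = _spectrum(T, pi, self.reversible)
        if abs(vals[0] - 1.0) > 1e-8:
            raise LamaError(f"leading eigenvalue {vals[0]!r} != 1")
        if np.any(np.abs(vals) > 1.0 + 1e-10):
            raise LamaError("spectral radius exceeds 1")
        self.eigenvalues = vals
        self.right_eigenvectors = right
        self.left_eigenvectors = left

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_transition_matrix(
        cls,
        T: np.ndarray,
        lag_time: float = 1.0,
        time_unit: str = "steps",
        pi: np.ndarray | None = None,
        reversible: bool | None = None,
    ) -> "MSMResults":
        """Wrap an explicitly given transition matrix (e.g. ground truth)."""
        T = np.asarray(T, dtype=float)
        if pi is None:
            pi = _leading_left_eigvec(T)
        if reversible is None:
            flux = pi[:, None] * T
            reversible = bool(np.max(np.abs(flux - flux.T)) < 1e-10)
        return cls(
            transition_matrix=T,
            stationary_distribution=np.asarray(pi, dtype=float),
            active_set=np.arange(T.shape[0]),
            lag_time=lag_time,
            time_unit=time_unit,
            reversible=reversible,
        )

    # -- basic properties --------------------------------------------------

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def is_reversible(self, tol: float = 1e-8) -> bool:
        flux = self.stationary_distribution[:, None] * self.transition_matrix
        return bool(np.max(np.abs(flux - flux.T)) < tol)

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied timescales t_i = −τ / ln λ_i for the slow processes.

        The stationary eigenvalue is excluded; non-positive (or complex,
        reported by magnitude with a warning) eigenvalues yield NaN.
        """
        vals = self.eigenvalues[1:None if k is None else k + 1]
        out = np.full(vals.shape, np.nan)
        for i, lam in enumerate(vals):
            if np.iscomplexobj(vals) and abs(lam.imag) > 1e-12:
                warnings.warn(
                    "complex eigenvalue encountered; using its magnitude "
                    "(consider the reversible estimator)"
                )
                lam = abs(lam)
            lam = float(np.real(lam))
            if 0.0 < lam < 1.0:
                out[i] = -self.lag_time / np.log(lam)
        return np.real(out)

    # -- downstream analyses (delegating to lama.coarse) -------------------

    def pcca(self, n_macrostates: int):
        from . import coarse
        return coarse.pcca_plus(self, n_macrostates)

    def tpt(self, source, sink):
        from . import coarse
        return coarse.tpt(self, source, sink)

    def sample_path(self, start_state: int, n_steps: int, seed: int = 0):
        from . import coarse
        return coarse.reconstruct_trajectory(self, start_state, n_steps, seed)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        ts = self.timescales(min(5, self.n_states - 1))
        lines = [
            "Markov State Model Results",
            "=" * 44,
            f"active microstates     : {self.n_states}",
            f"lag time               : {self.lag_time:g} {self.time_unit}"
            f" ({self.lag_frames} frames)",
            f"estimator              : "
            + ("reversible MLE" if self.reversible else "row normalisation"),
            f"total transition counts: "
            + (f"{self.counts_active.total:.0f}" if self.counts_active else "n/a"),
            f"stationary entropy     : "
            f"{-np.sum(self.stationary_distribution * np.log(np.maximum(self.stationary_distribution, 1e-300))):.3f} nats",
            "-" * 44,
            "slowest implied timescales (" + self.time_unit + "):",
        ]
        for i, t in enumerate(ts, start=2):
            lam = self.eigenvalues[i - 1]
            lam_str = f"{np.real(lam):+.6f}"
            t_str = f"{t:.4g}" if np.isfinite(t) else "undefined"
            lines.append(f"  t_{i}: {t_str:>12}   (λ_{i} = {lam_str})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Implied-timescale lag scan
# ---------------------------------------------------------------------------

@dataclass
class ImpliedTimescales:
    """t_i(τ) across candidate lags; flat curves indicate Markovianity."""

    lags: np.ndarray                  # physical units
    lag_frames: np.ndarray
    timescales: np.ndarray            # (n_lags, n_processes), NaN = undefined
    complex_flags: np.ndarray         # bool, any complex eigenvalue at that lag
    time_unit: str = "steps"


def implied_timescales(
    dtrajs: Sequence[np.ndarray],
    lags: Sequence[int],
    n_processes: int = 5,
    reversible: bool = False,
    frame_interval: float = 1.0,
    time_unit: str = "steps",
) -> ImpliedTimescales:
    """Build an MSM per lag and collect t_i = −τ / ln λ_{i+1}.

    ``lags`` are in frames and must be sorted ascending; timescales are
    returned in physical units (``frame_interval`` per frame).
    """
    lags = list(lags)
    if lags != sorted(lags):
        raise ValidationError("lags must be sorted ascending")
    rows, cflags = [], []
    for lag in lags:
        res = MarkovStateModel(
            dtrajs, lag=lag, frame_interval=frame_interval,
            time_unit=time_unit, reversible=reversible,
        ).fit()
        ts = res.timescales(n_processes)
        if ts.size < n_processes:
            ts = np.concatenate([ts, np.full(n_processes - ts.size, np.nan)])
        rows.append(ts[:n_processes])
        cflags.append(bool(np.any(np.abs(np.imag(res.eigenvalues)) > 1e-12)))
    return ImpliedTimescales(
        lags=np.asarray(lags, dtype=float) * frame_interval,
        lag_frames=np.asarray(lags),
        timescales=np.vstack(rows),
        complex_flags=np.asarray(cflags),
        time_unit=time_unit,
    )


# ---------------------------------------------------------------------------
# Stationary weights and free-energy projection
# ---------------------------------------------------------------------------

def frame_weights(results: MSMResults, labels: np.ndarray) -> np.ndarray:
    """Per-frame stationary weights: π(state) / n_frames(state).

    Frames in microstates outside the active set get weight 0; the result
    sums to ≤ 1 (equal to 1 when every frame is in the active set).
    """
    labels = np.asarray(labels, dtype=np.intp)
    n_full = int(labels.max()) + 1
    pi_full = np.zeros(max(n_full, int(results.active_set.max()) + 1))
    pi_full[results.active_set] = results.stationary_distribution
    counts = np.bincount(labels, minlength=pi_full.shape[0]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_state = np.where(counts > 0, pi_full / counts, 0.0)
    return per_state[labels]


@dataclass
class FreeEnergyLandscape:
    """Binned free energy, in kT, on a PC plane: F = −ln p, min-shifted to 0."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ma.MaskedArray     # (nx, ny); empty bins masked
    plane: tuple[int, int]

    @property
    def minimum(self) -> float:
        return float(self.free_energy.min())


def project_free_energy(
    pcs: np.ndarray,
    weights: np.ndarray,
    plane: tuple[int, int] = (0, 1),
    n_bins: int = 60,
) -> FreeEnergyLandscape:
    """Weighted 2D histogram on a PC plane turned into a free-energy map.

    ``weights`` are per-frame stationary weights (see :func:`frame_weights`);
    F_bin = −ln(p_bin) shifted so the minimum over occupied bins is 0, with
    empty bins masked rather than zeroed.
    """
    pcs = np.asarray(pcs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValidationError("weights must be non-negative")
    if weights.sum() <= 0:
        raise ValidationError("all frame weights are zero")
    x, y = pcs[:, plane[0]], pcs[:, plane[1]]
    H, xe, ye = np.histogram2d(x, y, bins=n_bins, weights=weights)
    p = H / H.sum()
    mask = p <= 0
    with np.errstate(divide="ignore"):
        F = -np.log(np.where(mask, 1.0, p))
    F = F - F[~mask].min()
    return FreeEnergyLandscape(
        x_edges=xe, y_edges=ye,
        free_energy=np.ma.masked_array(F, mask=mask),
        plane=plane,
    )


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov spot-check
# ---------------------------------------------------------------------------

def ck_test(
    dtrajs: Sequence[np.ndarray],
    lag: int,
    reversible: bool = False,
) -> float:
    """Frobenius distance between T(τ)² and the estimated T(2τ).

    Small values on Markovian data; the comparison is restricted to the
    intersection of the two active sets.
    """
    r1 = MarkovStateModel(dtrajs, lag=lag, reversible=reversible).fit()
    r2 = MarkovStateModel(dtrajs, lag=2 * lag, reversible=reversible).fit()
    common = np.intersect1d(r1.active_set, r2.active_set)
    i1 = np.searchsorted(r1.active_set, common)
    i2 = np.searchsorted(r2.active_set, common)
    A = np.linalg.matrix_power(r1.transition_matrix, 2)[np.ix_(i1, i1)]
    B = r2.transition_matrix[np.ix_(i2, i2)]
    return float(np.linalg.norm(A - B, ord="fro"))
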