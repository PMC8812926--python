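"""Synthetic inputs with the statistical structure of the target study.

The real ligand-binding data behind this pipeline are ensembles of many
short molecular-dynamics trajectories seeded along a steered (pulled)
unbinding path, showing metastable bound / partially-bound / dissociated
states, rare transitions between them, a fluctuating helix "gate" distance,
and head-group contact formation and breaking.  None of that raw data is
public, so this module generates stand-ins with known ground truth:

* :func:`sample_discrete_chain` — Markov chains from an exact transition
  matrix, the ground truth for transition-matrix estimator tests;
* :func:`simulate_langevin` — overdamped Brownian dynamics on built-in 2D
  multi-well potentials, a continuous stand-in for conformational sampling;
* :func:`simulate_toy_binding` — a 3D pseudo-receptor ring with a
  telegraph-switching gate and a ligand that can only cross the ring wall
  through an open gate, emulating lateral access through a transmembrane
  gap;
* :func:`steered_seed_emulator` — frames interpolated along a bound→unbound
  ligand path and subsampled without replacement, mimicking seeding of
  production runs from a steered unbinding trajectory (the pulling physics
  itself is out of scope);
* :class:`StudyManifest` — the bookkeeping of the emulated study protocol
  (how many seeds per docking model, run lengths, sampling interval), from
  which aggregate simulated time and frame counts follow.

Every generator draws from one named :class:`numpy.random.Generator` seeded
from its spec; results are bit-reproducible for a fixed spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import SimulationError, ValidationError
from .trajio import Topology, TrajectoryEnsemble

__all__ = [
    "DiscreteChainSpec",
    "LangevinSpec",
    "ToyReceptorSpec",
    "StudyManifest",
    "ToyBindingResult",
    "sample_discrete_chain",
    "simulate_langevin",
    "simulate_toy_binding",
    "steered_seed_emulator",
    "stationary_distribution",
    "POTENTIALS",
]


# ---------------------------------------------------------------------------
# Discrete Markov chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteChainSpec:
    """Exact-kinetics Markov chain: ground truth for MSM estimators."""

    transition_matrix: np.ndarray
    n_trajectories: int
    n_steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "transition_matrix", T)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValidationError("transition_matrix must be square")
        if np.any(T < 0) or np.any(T > 1):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        rowsums = T.sum(axis=1)
        bad = np.flatnonzero(np.abs(rowsums - 1.0) > 1e-12)
        if bad.size:
            raise ValidationError(
                f"row {bad[0]} of transition_matrix sums to {rowsums[bad[0]]!r}, not 1"
            )
        if self.n_trajectories < 1 or self.n_steps < 1:
            raise ValidationError("n_trajectories and n_steps must be positive")


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left eigenvector)."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_discrete_chain(
    spec: DiscreteChainSpec,
    start_states: int | Sequence[int] | None = None,
) -> list[np.ndarray]:
    """Sample ``spec.n_trajectories`` state sequences of length ``n_steps + 1``.

    ``start_states`` may be a single state applied to every trajectory or one
    state per trajectory; the default is state 0.
    """
    T = spec.transition_matrix
    n = T.shape[0]
    rng = np.random.default_rng(spec.seed)
    if start_states is None:
        starts = np.zeros(spec.n_trajectories, dtype=np.intp)
    else:
        starts = np.broadcast_to(
            np.asarray(start_states, dtype=np.intp), (spec.n_trajectories,)
        ).copy()
    if starts.min() < 0 or starts.max() >= n:
        raise ValidationError("start state out of range")

    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    states = np.empty((spec.n_trajectories, spec.n_steps + 1), dtype=np.intp)
    states[:, 0] = starts
    u = rng.random((spec.n_trajectories, spec.n_steps))
    if spec.n_trajectories == 1:
        row_cum = cum
        s = int(starts[0])
        seq = states[0]
        uu = u[0]
        for t in range(spec.n_steps):
            s = int(np.searchsorted(row_cum[s], uu[t], side="right"))
            seq[t + 1] = s
    else:
        for t in range(spec.n_steps):
            states[:, t + 1] = (cum[states[:, t]] < u[:, t, None]).sum(axis=1)
    return [states[i].copy() for i in range(spec.n_trajectories)]


# ---------------------------------------------------------------------------
# Overdamped Langevin dynamics on 2D potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Potential:
    name: str
    energy: Callable[[np.ndarray, dict], np.ndarray]
    gradient: Callable[[np.ndarray, dict], np.ndarray]
    box: float                     # simulation box is [-box, box]^2
    wells: tuple[tuple[float, float], ...]


def _flat_U(x, p):
    return np.zeros(x.shape[:-1])


def _flat_grad(x, p):
    return np.zeros_like(x)


def _harmonic_U(x, p):
    k = p.get("k", 1.0)
    return 0.5 * k * np.sum(x**2, axis=-1)


def _harmonic_grad(x, p):
    return p.get("k", 1.0) * x


def _double_U(x, p):
    h = p.get("barrier", 1.0)
    return h * (x[..., 0] ** 2 - 1.0) ** 2 + 0.5 * x[..., 1] ** 2


def _double_grad(x, p):
    h = p.get("barrier", 1.0)
    g = np.empty_like(x)
    g[..., 0] = 4.0 * h * x[..., 0] * (x[..., 0] ** 2 - 1.0)
    g[..., 1] = x[..., 1]
    return g


def _triple_U(x, p):
    # wells at x = -2, 0, +2; barrier height ~9.48*c at x = +-2/sqrt(3)
    c = p.get("scale", 0.1)
    xx = x[..., 0]
    return c * (xx**6 - 8.0 * xx**4 + 16.0 * xx**2) + 0.5 * x[..., 1] ** 2


def _triple_grad(x, p):
    c = p.get("scale", 0.1)
    xx = x[..., 0]
    g = np.empty_like(x)
    g[..., 0] = c * (6.0 * xx**5 - 32.0 * xx**3 + 32.0 * xx)
    g[..., 1] = x[..., 1]
    return g


POTENTIALS: dict[str, _Potential] = {
    "flat": _Potential("flat", _flat_U, _flat_grad, box=50.0, wells=((0.0, 0.0),)),
    "harmonic": _Potential("harmonic", _harmonic_U, _harmonic_grad, box=50.0,
                           wells=((0.0, 0.0),)),
    "double-well": _Potential("double-well", _double_U, _double_grad, box=4.0,
                              wells=((-1.0, 0.0), (1.0, 0.0))),
    "triple-well": _Potential("triple-well", _triple_U, _triple_grad, box=4.0,
                              wells=((-2.0, 0.0), (0.0, 0.0), (2.0, 0.0))),
}


@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped Brownian dynamics on a built-in bounded 2D potential."""

    potential: str
    diffusion_coefficient: float
    timestep: float
    n_steps: int
    n_trajectories: int
    seed: int = 0
    params: dict = field(default_factory=dict)
    start_points: tuple | None = None    # (n_trajectories, 2); default: wells round-robin

    def __post_init__(self) -> None:
        if self.potential not in POTENTIALS:
            raise ValidationError(
                f"unknown potential {self.potential!r}; "
                f"available: {sorted(POTENTIALS)}"
            )
        if self.timestep <= 0:
            raise ValidationError("timestep must be > 0")
        if self.diffusion_coefficient <= 0:
            raise ValidationError("diffusion_coefficient must be > 0")
        if self.n_steps < 1 or self.n_trajectories < 1:
            raise ValidationError("n_steps and n_trajectories must be positive")


def simulate_langevin(spec: LangevinSpec) -> TrajectoryEnsemble:
    """Euler–Maruyama integration: x' = x − ∇U(x)·dt + sqrt(2·D·dt)·ξ.

    The 2D points are emitted as single-pseudo-atom 3D frames (z = 0) so
    they flow through the same featurization and observables code as
    molecular coordinates.  A trajectory escaping the potential's declared
    box raises :class:`SimulationError` advising a smaller timestep.
    """
    pot = POTENTIALS[spec.potential]
    rng = np.random.default_rng(spec.seed)
    dt = spec.timestep
    sigma = math.sqrt(2.0 * spec.diffusion_coefficient * dt)

    if spec.start_points is not None:
        x = np.array(spec.start_points, dtype=float).reshape(spec.n_trajectories, 2)
    else:
        wells = np.asarray(pot.wells, dtype=float)
        x = wells[np.arange(spec.n_trajectories) % len(wells)].copy()

    out = np.empty((spec.n_trajectories, spec.n_steps + 1, 2))
    out[:, 0] = x
    for t in range(spec.n_steps):
        x = x - pot.gradient(x, spec.params) * dt + sigma * rng.standard_normal(x.shape)
        if np.any(np.abs(x) > pot.box):
            raise SimulationError(
                f"trajectory escaped the [-{pot.box}, {pot.box}]^2 box at step "
                f"{t + 1}; use a smaller timestep"
            )
        out[:, t + 1] = x

    coords = np.zeros((spec.n_trajectories, spec.n_steps + 1, 1, 3))
    coords[..., 0, :2] = out
    top = Topology(
        names=["P"], resnames=["PNT"], resids=[1], chains=["A"],
        groups={"particle": np.array([0])},
    )
    return TrajectoryEnsemble(
        coords=[coords[i] for i in range(spec.n_trajectories)],
        frame_interval_ps=dt,
        topology=top,
    )


# ---------------------------------------------------------------------------
# Gated receptor-ligand toy system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyReceptorSpec:
    """Pseudo-receptor ring with a switching gate and one diffusing ligand.

    The receptor is a ring of pseudo-atoms of radius ``ring_radius`` in the
    z = 0 plane.  Two ring positions (``gate_indices``) form a gate whose
    separation follows a two-state (open/closed) telegraph process with
    Gaussian jitter, emulating the spontaneous opening and closing of a
    membrane-facing helix gap.  The ligand performs biased diffusion with an
    attractive Gaussian well at ``ligand_site`` and may cross the ring wall
    (a cylinder of radius ``ring_radius``) only where the gate is, and only
    while the instantaneous gate separation exceeds
    ``gate_cross_threshold``.  While the ligand is inside, the gate is held
    open, so bound-state gap widths concentrate near ``gate_open_width``.
    """

    n_ring_atoms: int = 12
    gate_indices: tuple[int, int] = (0, 1)
    gate_open_width: float = 12.0       # Å
    gate_closed_width: float = 4.0      # Å
    gate_switch_rate: float = 0.005     # per-step switching probability
    ligand_site: tuple[float, float, float] = (0.0, 0.0, 0.0)
    binding_well_depth: float = 3.0     # dimensionless
    noise_scale: float = 0.8            # Å per-step displacement std
    n_steps: int = 100_000
    seed: int = 0
    ring_radius: float = 10.0           # Å
    gate_cross_threshold: float = 7.0   # Å; closed + jitter stays well below
    gate_jitter: float = 0.3            # Å std on the gate separation
    well_width: float = 3.0             # Å, Gaussian well sigma
    gate_start_open: bool = False
    ligand_start: tuple[float, float, float] | None = None
    save_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_ring_atoms < 6:
            raise ValidationError("n_ring_atoms must be >= 6")
        i, j = self.gate_indices
        if not (0 <= i < self.n_ring_atoms and 0 <= j < self.n_ring_atoms and i != j):
            raise ValidationError("gate_indices must be two distinct ring positions")
        if not (self.gate_open_width > self.gate_closed_width > 0):
            raise ValidationError("require gate_open_width > gate_closed_width > 0")
        if not (0 <= self.gate_switch_rate < 1):
            raise ValidationError("gate_switch_rate must lie in [0, 1)")
        if not (self.gate_closed_width < self.gate_cross_threshold <= self.gate_open_width):
            raise ValidationError(
                "gate_cross_threshold must lie between closed and open widths"
            )
        if self.binding_well_depth < 0:
            raise ValidationError("binding_well_depth must be >= 0")
        if self.noise_scale <= 0 or self.n_steps < 1:
            raise ValidationError("noise_scale must be > 0 and n_steps >= 1")
        if self.save_stride < 1:
            raise ValidationError("save_stride must be >= 1")


@dataclass
class ToyBindingResult:
    """Output of :func:`simulate_toy_binding`.

    Frames are saved every ``save_stride`` steps; entry/exit events are
    counted at full step resolution.
    """

    ensemble: TrajectoryEnsemble
    topology: Topology
    gate_width: np.ndarray       # per saved frame, Å
    gate_open: np.ndarray        # per saved frame, bool
    bound: np.ndarray            # per saved frame, bool
    n_entry_events: int
    n_exit_events: int


def simulate_toy_binding(spec: ToyReceptorSpec) -> ToyBindingResult:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ring_atoms
    R = spec.ring_radius
    angles = 2.0 * math.pi * np.arange(n) / n
    base_ring = np.stack(
        [R * np.cos(angles), R * np.sin(angles), np.zeros(n)], axis=1
    )
    gi, gj = spec.gate_indices
    theta0 = math.atan2(
        base_ring[gi, 1] + base_ring[gj, 1], base_ring[gi, 0] + base_ring[gj, 0]
    )
    site = np.asarray(spec.ligand_site, dtype=float)

    pos = (
        np.array(spec.ligand_start, dtype=float)
        if spec.ligand_start is not None
        else np.array([1.6 * R * math.cos(theta0), 1.6 * R * math.sin(theta0), 0.0])
    )
    gate_is_open = spec.gate_start_open
    r_conf = 2.5 * R     # soft outer confinement radius
    k_conf = 0.5
    k_z = 0.8      # |1 - k_z| < 1 keeps the unit-step z tether stable
    inv_w2 = 1.0 / spec.well_width**2

    n_saved = spec.n_steps // spec.save_stride + 1
    frames = np.empty((n_saved, n + 1, 3))
    gate_width_s = np.empty(n_saved)
    gate_open_s = np.empty(n_saved, dtype=bool)
    bound_s = np.empty(n_saved, dtype=bool)

    # pre-draw random streams in blocks to keep the step loop cheap
    switch_u = rng.random(spec.n_steps)
    gate_eps = rng.normal(0.0, spec.gate_jitter, spec.n_steps + 1)
    lig_noise = rng.normal(0.0, spec.noise_scale, (spec.n_steps, 3))
    ring_noise_scale = spec.noise_scale * 0.25   # mild thermal jitter on the ring

    def gate_atoms(width: float) -> np.ndarray:
        half = math.asin(min(width / (2.0 * R), 1.0))
        a1, a2 = theta0 - half, theta0 + half
        return np.array(
            [[R * math.cos(a1), R * math.sin(a1), 0.0],
             [R * math.cos(a2), R * math.sin(a2), 0.0]]
        )

    def is_bound(p: np.ndarray) -> bool:
        return float(np.linalg.norm(p - site)) < R

    def save(k: int, width: float) -> None:
        ring = base_ring + rng.normal(0.0, ring_noise_scale, base_ring.shape)
        ga = gate_atoms(width)
        ring[gi], ring[gj] = ga[0], ga[1]
        frames[k, :n] = ring
        frames[k, n] = pos
        gate_width_s[k] = width
        gate_open_s[k] = gate_is_open
        bound_s[k] = is_bound(pos)

    bound_now = is_bound(pos)
    n_entry = n_exit = 0
    width = (spec.gate_open_width if gate_is_open else spec.gate_closed_width) + gate_eps[0]
    save(0, width)
    k_saved = 1

    for t in range(spec.n_steps):
        # telegraph gate; held open while the ligand is inside
        if bound_now:
            gate_is_open = True
        elif switch_u[t] < spec.gate_switch_rate:
            gate_is_open = not gate_is_open
        width = (
            spec.gate_open_width if gate_is_open else spec.gate_closed_width
        ) + gate_eps[t + 1]

        # ligand forces: Gaussian binding well + outer confinement + z tether
        d = pos - site
        r2 = float(d @ d)
        force = -spec.binding_well_depth * math.exp(-0.5 * r2 * inv_w2) * inv_w2 * d
        r_xy = math.hypot(pos[0], pos[1])
        if r_xy > r_conf:
            force[:2] -= k_conf * (r_xy - r_conf) * pos[:2] / r_xy
        force[2] -= k_z * pos[2]
        new = pos + force + lig_noise[t]

        # wall rule: the ring is a cylinder; radial crossings are allowed only
        # through the gate aperture while the separation exceeds the threshold
        r_new = math.hypot(new[0], new[1])
        if (r_xy - R) * (r_new - R) < 0.0:
            allowed = width >= spec.gate_cross_threshold
            if allowed:
                mid = 0.5 * (pos[:2] + new[:2])
                ang = math.atan2(mid[1], mid[0])
                dang = math.atan2(math.sin(ang - theta0), math.cos(ang - theta0))
                half = math.asin(min(width / (2.0 * R), 1.0))
                allowed = abs(dang) <= half
            if not allowed:
                new = pos   # rejected: the wall is impenetrable off-gate
        pos = new

        b = is_bound(pos)
        if b and not bound_now:
            n_entry += 1
        elif bound_now and not b:
            n_exit += 1
        bound_now = b

        if (t + 1) % spec.save_stride == 0:
            save(k_saved, width)
            k_saved += 1

    names = [f"R{i}" for i in range(n)] + ["L"]
    resnames = ["RNG"] * n + ["LIG"]
    resids = list(range(1, n + 1)) + [n + 1]
    chains = ["A"] * n + ["B"]
    top = Topology(
        names=names, resnames=resnames, resids=resids, chains=chains,
        groups={
            "receptor": np.arange(n),
            "gate": np.array([gi, gj]),
            "ligand": np.array([n]),
            "ligand_heavy": np.array([n]),
        },
        markers={"gate": (gi + 1, gj + 1)},
    )
    ens = TrajectoryEnsemble(
        coords=[frames[:k_saved]],
        frame_interval_ps=float(spec.save_stride),
        ids=["toy_binding"],
        topology=top,
    )
    return ToyBindingResult(
        ensemble=ens,
        topology=top,
        gate_width=gate_width_s[:k_saved],
        gate_open=gate_open_s[:k_saved],
        bound=bound_s[:k_saved],
        n_entry_events=n_entry,
        n_exit_events=n_exit,
    )


# ---------------------------------------------------------------------------
# Steered-pull seeding emulator
# ---------------------------------------------------------------------------

def steered_seed_emulator(
    bound_frame: np.ndarray,
    unbound_frame: np.ndarray,
    n_seeds: int,
    seed: int = 0,
    grid_size: int = 15_000,
    jitter: float = 0.0,
    moving_atoms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeds along an interpolated unbinding path, sampled without replacement.

    A dense grid of ``grid_size`` frames is built by linear interpolation
    from the bound pose to the unbound pose (only ``moving_atoms`` move if
    given, mimicking a ligand pulled off a fixed receptor), ``n_seeds``
    distinct grid frames are drawn uniformly at random without replacement,
    and Gaussian jitter of the given std (Å) is added to the moving atoms.

    Returns ``(frames, grid_indices)`` with frames sorted by grid position.
    """
    bound = np.asarray(bound_frame, dtype=float)
    unbound = np.asarray(unbound_frame, dtype=float)
    if bound.shape != unbound.shape:
        raise ValidationError("bound and unbound frames must share a shape")
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    if n_seeds > grid_size:
        raise ValidationError(
            f"n_seeds ({n_seeds}) exceeds the interpolation grid ({grid_size})"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(grid_size, size=n_seeds, replace=False))
    t = idx / (grid_size - 1) if grid_size > 1 else np.zeros(1)

    if moving_atoms is None:
        delta = unbound - bound
        frames = bound[None] + t[:, None, None] * delta[None]
        if jitter > 0:
            frames = frames + rng.normal(0.0, jitter, frames.shape)
    else:
        moving_atoms = np.asarray(moving_atoms, dtype=np.intp)
        frames = np.repeat(bound[None], n_seeds, axis=0)
        delta = unbound[moving_atoms] - bound[moving_atoms]
        frames[:, moving_atoms] = bound[None, moving_atoms] + t[:, None, None] * delta[None]
        if jitter > 0:
            frames[:, moving_atoms] += rng.normal(
                0.0, jitter, (n_seeds, moving_atoms.size, 3)
            )
    return frames, idx


# ---------------------------------------------------------------------------
# Study manifest (protocol bookkeeping)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyManifest:
    """Protocol bookkeeping of the emulated simulation study.

    Defaults reproduce the emulated campaign: production runs of 100 ns
    sampled every 10 ps are seeded from 379 + 335 snapshots drawn from a
    steered-unbinding grid of 15,000 structures (2 docking models x 5 pulls
    of 50 ns, 1,500 structures kept per pull), and a 100 µs trajectory is
    reconstructed from the fitted model as 10,000 jumps at a 10 ns lag.
    """

    seeds_per_model: tuple[tuple[str, int], ...] = (("model1", 379), ("model2", 335))
    production_ns: float = 100.0
    frame_interval_ps: float = 10.0
    steered_models: int = 2
    steered_runs_per_model: int = 5
    steered_run_ns: float = 50.0
    steered_samples_per_run: int = 1500
    lag_ns: float = 10.0
    reconstruction_steps: int = 10_000

    @property
    def n_seeds_total(self) -> int:
        return sum(n for _, n in self.seeds_per_model)

    def model_seeds(self, name: str) -> int:
        for m, n in self.seeds_per_model:
            if m == name:
                return n
        raise KeyError(name)

    def model_time_us(self, name: str) -> float:
        return self.model_seeds(name) * self.production_ns / 1000.0

    @property
    def total_time_us(self) -> float:
        """Aggregate production simulation time in µs."""
        return self.n_seeds_total * self.production_ns / 1000.0

    @property
    def frames_per_run(self) -> int:
        return int(round(self.production_ns * 1000.0 / self.frame_interval_ps))

    @property
    def n_production_frames(self) -> int:
        return self.n_seeds_total * self.frames_per_run

    @property
    def steered_grid_size(self) -> int:
        """Structures on the steered unbinding grid: models × pulls × samples."""
        return (self.steered_models * self.steered_runs_per_model
                * self.steered_samples_per_run)

    @property
    def reconstruction_duration_us(self) -> float:
        return self.reconstruction_steps * self.lag_ns / 1000.0
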