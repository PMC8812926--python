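"""Geometric time-series and summaries over trajectory ensembles.

Distances are in Å.  Series carry (trajectory, frame) bookkeeping so they
line up with feature matrices and microstate labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .trajio import TrajectoryEnsemble

__all__ = [
    "ObservableSeries",
    "ConditionedHistogram",
    "pair_distance",
    "min_group_distance",
    "contact_timeline",
    "detect_interacting_residues",
    "moving_average",
    "state_conditioned_histogram",
]


@dataclass
class ObservableSeries:
    """Named per-frame values with bookkeeping and optional annotations."""

    name: str
    values: np.ndarray
    traj_idx: np.ndarray
    frame_idx: np.ndarray
    unit: str = "A"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"series {self.name!r} contains non-finite values")
        if self.values.shape[0] != self.traj_idx.shape[0]:
            raise ValidationError("bookkeeping length mismatch")

    def __len__(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "ObservableSeries":
        return ObservableSeries(
            name=name or self.name,
            values=values,
            traj_idx=self.traj_idx,
            frame_idx=self.frame_idx,
            unit=self.unit,
            annotations=dict(self.annotations),
        )

    def to_frame(self):
        """Export as a pandas DataFrame (trajectory, frame, value)."""
        import pandas as pd
        return pd.DataFrame(
            {"trajectory": self.traj_idx, "frame": self.frame_idx,
             self.name: self.values}
        )


def _resolve(ensemble: TrajectoryEnsemble, selection) -> np.ndarray:
    if isinstance(selection, str):
        if ensemble.topology is None:
            raise ValidationError("string selections require a topology")
        return ensemble.topology.select(selection)
    return np.asarray(selection, dtype=np.intp)


def pair_distance(ensemble: TrajectoryEnsemble, atom_a, atom_b,
                  name: str = "pair_distance") -> ObservableSeries:
    """Per-frame Euclidean distance between two single atoms, Å.

    Each selection must resolve to exactly one atom; use
    :func:`min_group_distance` for groups.
    """
    ia, ib = _resolve(ensemble, atom_a), _resolve(ensemble, atom_b)
    if ia.size != 1 or ib.size != 1:
        raise ValidationError(
            f"pair_distance needs single atoms (got {ia.size} and {ib.size}); "
            "use min_group_distance for groups"
        )
    xyz, traj_idx, frame_idx = ensemble.stacked()
    d = np.linalg.norm(xyz[:, ia[0]] - xyz[:, ib[0]], axis=1)
    return ObservableSeries(name, d, traj_idx, frame_idx)


def min_group_distance(ensemble: TrajectoryEnsemble, group_a, group_b,
                       name: str = "min_distance") -> ObservableSeries:
    """Per-frame minimum distance over all cross pairs of two atom groups."""
    ia, ib = _resolve(ensemble, group_a), _resolve(ensemble, group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValidationError("both groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValidationError("groups overlap; cross-group distance is ill-defined")
    xyz, traj_idx, frame_idx = ensemble.stacked()
    diff = xyz[:, ia, None, :] - xyz[:, None, ib, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1)).min(axis=(1, 2))
    return ObservableSeries(name, d, traj_idx, frame_idx)


def contact_timeline(series: ObservableSeries, threshold: float):
    """Boolean contact series (value ≤ threshold) plus contact fraction."""
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    contacts = series.values <= threshold
    return contacts, float(contacts.mean())


def detect_interacting_residues(
    ensemble: TrajectoryEnsemble,
    ligand_selection,
    receptor_residues,
    min_d: float = 1.5,
    max_d: float = 5.0,
):
    """Residues with any ligand-residue atom distance inside [min_d, max_d].

    Returns ``(residue_number, contact_fraction)`` pairs sorted by fraction,
    descending.  The default 1.5-5.0 Å window covers hydrogen-bond and
    hydrophobic contact distances.
    """
    if not (0 < min_d < max_d):
        raise ValidationError("require 0 < min_d < max_d")
    receptor_residues = list(receptor_residues)
    if not receptor_residues:
        raise ValidationError("receptor residue set is empty")
    if ensemble.topology is None:
        raise ValidationError("interacting-residue detection requires a topology")
    lig = _resolve(ensemble, ligand_selection)
    xyz, _, _ = ensemble.stacked()
    resids = np.asarray(ensemble.topology.resids)
    out = []
    for rid in receptor_residues:
        atoms = np.setdiff1d(np.flatnonzero(resids == rid), lig)
        if atoms.size == 0:
            continue
        diff = xyz[:, lig, None, :] - xyz[:, None, atoms, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        qualifies = np.any((d >= min_d) & (d <= max_d), axis=(1, 2))
        frac = float(qualifies.mean())
        if frac > 0:
            out.append((int(rid), frac))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def moving_average(series: ObservableSeries, window: int) -> ObservableSeries:
    """Trailing mean over ``window`` frames, per trajectory.

    The first ``window − 1`` entries of each trajectory average over the
    available prefix.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    values = np.empty_like(series.values)
    for t in np.unique(series.traj_idx):
        m = series.traj_idx == t
        v = series.values[m]
        if window > v.size:
            raise ValidationError(
                f"window ({window}) exceeds trajectory length ({v.size})"
            )
        c = np.concatenate([[0.0], np.cumsum(v)])
        idx = np.arange(1, v.size + 1)
        lo = np.maximum(idx - window, 0)
        values[m] = (c[idx] - c[lo]) / (idx - lo)
    return series.with_values(values, name=f"{series.name}_ma{window}")


@dataclass
class ConditionedHistogram:
    """Normalized histograms of a series split by a boolean condition."""

    edges: np.ndarray
    hist_true: np.ndarray | None
    hist_false: np.ndarray | None
    summary: dict    # per-condition min/max/mean


def state_conditioned_histogram(
    series: ObservableSeries,
    condition: np.ndarray,
    n_bins: int = 40,
) -> ConditionedHistogram:
    """Histograms of the series in the two condition classes (e.g. bound vs
    unbound), on shared bin edges, with per-class extrema and means."""
    condition = np.asarray(condition, dtype=bool)
    if condition.shape[0] != len(series):
        raise ValidationError("condition length must match the series")
    edges = np.histogram_bin_edges(series.values, bins=n_bins)
    out = {}
    hists = {}
    for flag in (True, False):
        vals = series.values[condition == flag]
        key = "true" if flag else "false"
        if vals.size == 0:
            warnings.warn(f"condition class {key!r} is empty; histogram omitted")
            hists[key] = None
            continue
        h, _ = np.histogram(vals, bins=edges, density=True)
        hists[key] = h
        out[key] = {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
            "n": int(vals.size),
        }
    return ConditionedHistogram(
        edges=edges, hist_true=hists["true"], hist_false=hists["false"],
        summary=out,
    )
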