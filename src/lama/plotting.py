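"""Rendering helpers for landscapes, lag scans and observable timelines."""

from __future__ import annotations

import numpy as np

from .msm import FreeEnergyLandscape, ImpliedTimescales
from .observables import ObservableSeries


def plot_free_energy(fel: FreeEnergyLandscape, ax=None, cmap="viridis"):
    """Filled free-energy map on a PC plane; empty bins stay blank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    X, Y = np.meshgrid(fel.x_edges, fel.y_edges, indexing="ij")
    m = ax.pcolormesh(X, Y, fel.free_energy, cmap=cmap)
    ax.set_xlabel(f"PC{fel.plane[0] + 1}")
    ax.set_ylabel(f"PC{fel.plane[1] + 1}")
    ax.figure.colorbar(m, ax=ax, label="free energy (kT)")
    return ax


def plot_implied_timescales(its: ImpliedTimescales, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i in range(its.timescales.shape[1]):
        ax.plot(its.lags, its.timescales[:, i], marker="o", label=f"t{i + 2}")
    ax.plot(its.lags, its.lags, "k--", lw=0.8)   # processes below τ are unresolved
    ax.set_xlabel(f"lag time ({its.time_unit})")
    ax.set_ylabel(f"implied timescale ({its.time_unit})")
    ax.set_yscale("log")
    ax.legend()
    return ax


def plot_series(series: ObservableSeries, ax=None, threshold: float | None = None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(len(series)), series.values, lw=0.6)
    if threshold is not None:
        ax.axhline(threshold, color="r", lw=0.8, ls="--")
    ax.set_xlabel("frame")
    ax.set_ylabel(f"{series.name} ({series.unit})")
    return ax
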