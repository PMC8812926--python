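"""YAML pipeline configuration.

The config file has up to three sections::

    toymodel:       # specs for the synthetic generators
      chain:    {transition_matrix: [[0.9, 0.1], [0.1, 0.9]], n_trajectories: 10, n_steps: 1000, seed: 1}
      langevin: {potential: double-well, diffusion_coefficient: 0.5, timestep: 0.01, n_steps: 5000, n_trajectories: 4, seed: 1}
      binding:  {n_steps: 50000, seed: 1}
      seeds:    {n_seeds: 714, grid_size: 15000, jitter: 0.1, seed: 1}
    selections:     # named selection expressions, attached to the topology
      ligand_heavy: "name L"
    pipeline:       # end-to-end analysis parameters
      trajectories: ["runs/*.pdb"]
      topology: runs/top.pdb
      frame_interval_ps: 10.0
      selection: null          # expression; default: all atoms
      n_landmarks: 500
      max_frames_for_medoid: 10000
      n_components: 10
      k: 1000
      lag: 1                   # frames
      its_lags: [1, 2, 5, 10]
      reversible: true
      n_macrostates: 7
      fel: {plane: [0, 1], n_bins: 60}
      tpt: {source: [0], sink: [5]}
      seed: 0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .exceptions import ValidationError
from .toymodel import DiscreteChainSpec, LangevinSpec, ToyReceptorSpec


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg


def chain_spec(cfg: dict) -> DiscreteChainSpec:
    return DiscreteChainSpec(**cfg)


def langevin_spec(cfg: dict) -> LangevinSpec:
    return LangevinSpec(**cfg)


def binding_spec(cfg: dict) -> ToyReceptorSpec:
    cfg = dict(cfg)
    for key in ("gate_indices", "ligand_site", "ligand_start"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = tuple(cfg[key])
    return ToyReceptorSpec(**cfg)
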