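"""Shared fixtures: small ground-truth chains and toy systems."""

import numpy as np
import pytest

from lama.toymodel import (
    DiscreteChainSpec,
    LangevinSpec,
    ToyReceptorSpec,
    sample_discrete_chain,
    simulate_langevin,
    simulate_toy_binding,
)


@pytest.fixture(scope="session")
def three_state_T():
    return np.array(
        [[0.90, 0.08, 0.02],
         [0.10, 0.80, 0.10],
         [0.05, 0.15, 0.80]]
    )


@pytest.fixture(scope="session")
def three_state_dtrajs(three_state_T):
    """100 trajectories x 10,000 steps: one million sampled transitions."""
    spec = DiscreteChainSpec(three_state_T, n_trajectories=100, n_steps=10_000, seed=11)
    return sample_discrete_chain(spec)


@pytest.fixture(scope="session")
def metastable4_T():
    eps = 0.02
    T = np.array(
        [[0.90, 0.08, eps / 2, eps / 2],
         [0.08, 0.90, eps / 2, eps / 2],
         [eps / 2, eps / 2, 0.90, 0.08],
         [eps / 2, eps / 2, 0.08, 0.90]]
    )
    return T / T.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def metastable4_dtrajs(metastable4_T):
    spec = DiscreteChainSpec(metastable4_T, n_trajectories=100, n_steps=10_000, seed=2)
    return sample_discrete_chain(spec)


@pytest.fixture(scope="session")
def triple_well_ensemble():
    """Brownian dynamics on the triple-well surface, hopping between wells."""
    spec = LangevinSpec(
        "triple-well", diffusion_coefficient=0.45, timestep=0.01,
        n_steps=6000, n_trajectories=12, seed=3,
    )
    return simulate_langevin(spec)


@pytest.fixture(scope="session")
def toy_gated_run():
    """Gated receptor-ligand toy with switching gate; binding and unbinding."""
    spec = ToyReceptorSpec(
        gate_switch_rate=0.02, gate_start_open=True,
        n_steps=200_000, seed=5, save_stride=50,
    )
    return simulate_toy_binding(spec)
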