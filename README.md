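# lama — lateral-access Markov analysis

`lama` reconstructs slow ligand-binding kinetics from ensembles of many
short molecular trajectories, the regime typical of membrane-receptor
binding studies where a single continuous simulation can never reach the
microsecond events of interest.  It targets the *lateral access* problem —
a lipophilic ligand entering a receptor's buried binding pocket sideways,
from the membrane, through a transiently open gap between transmembrane
helices — but the pipeline is generic for any system sampled as short
seeded trajectories.

The pipeline is the standard Markov-state-model (MSM) stack:

1. **Featurization** — each frame becomes its vector of RMSD values to a
   fixed set of reference structures (landmarks) chosen by k-medoids on the
   pairwise-RMSD metric (default 500 landmarks).
2. **Compression & microstates** — PCA to 10 principal components,
   k-means into 1,000 microstates in PC space.
3. **MSM estimation** — transitions counted at lag τ, restricted to the
   largest strongly connected microstate set, normalised into the
   row-stochastic T(τ); the lag is chosen where the implied timescales
   t_i = −τ / ln λ_i(τ) flatten.
4. **Coarse analysis** — PCCA+ metastable macrostates, stationary
   distribution π and free-energy landscapes F = −ln p on PC planes,
   transition-path-theory committors/fluxes/pathways, long reconstructed
   trajectories sampled from T, and whole-trajectory bootstrap robustness.

Because raw data of this kind are rarely deposited, `lama.toymodel`
generates synthetic inputs with known ground truth and the same
statistical structure: exact Markov chains, Brownian dynamics on
multi-well potentials, a gated receptor–ligand toy system whose ligand can
only cross the receptor wall through a stochastically opening gate, and an
emulator of steered-unbinding seeding (frames interpolated along a
bound→unbound path and subsampled without replacement).

## Worked example

Brownian dynamics on a triple-well potential, run through the full
pipeline (the ground truth is three metastable states):

```python
import numpy as np
from lama import *
from lama.toymodel import LangevinSpec, simulate_langevin

spec = LangevinSpec("triple-well", diffusion_coefficient=0.45,
                    timestep=0.01, n_steps=6000, n_trajectories=12, seed=3)
ens = simulate_langevin(spec)

landmarks = select_landmarks(ens, n_landmarks=30, max_frames_for_medoid=400, seed=0)
features = featurize_ensemble(ens, landmarks)
pca = fit_pca(features, n_components=2)
pcs = pca.transform(features)
micro = cluster_microstates(pcs, k=50, seed=0, n_init=3,
                            traj_idx=features.traj_idx, frame_idx=features.frame_idx)

model = MarkovStateModel(micro.discrete_trajectories(), lag=20,
                         frame_interval=0.01, time_unit="time units", reversible=True)
res = model.fit()
print(res.summary())

macro = res.pcca(3)
print("macrostate populations:", np.round(macro.populations, 3))

flux = res.tpt(macro.members(0), macro.members(2))
print("total A->B reactive flux:", f"{flux.total_flux:.3e}")
```

prints

```
Markov State Model Results
============================================
active microstates     : 50
lag time               : 0.2 time units (20 frames)
estimator              : reversible MLE
total transition counts: 71772
stationary entropy     : 3.692 nats
--------------------------------------------
slowest implied timescales (time units):
  t_2:        8.828   (λ_2 = +0.977600)
  t_3:        3.694   (λ_3 = +0.947301)
  t_4:       0.4375   (λ_4 = +0.633086)
  t_5:       0.3966   (λ_5 = +0.603956)
  t_6:       0.3651   (λ_6 = +0.578209)
macrostate populations: [0.221 0.316 0.463]
total A->B reactive flux: 9.757e-03
```

The spectrum reads directly: two slow processes (t₂, t₃) separated from
the fast bath (t₄ onwards) means three metastable states — exactly the
three wells.  The macrostate populations are the equilibrium well
occupancies implied by π, and the reactive flux quantifies how probability
flows from the first well to the third through the middle one.  PCCA+
lumping of the 50 microstates recovers the true well identity of ≥95% of
frames (this is one of the package's standing acceptance checks).

A thin CLI wraps the same calls: `lama toy ...` for generators,
`lama io convert|validate` for trajectory files (multi-frame PDB, XYZ, and
a fast binary coordinate archive), and `lama run --config cfg.yaml --out
dir` for the end-to-end pipeline (see `lama.config` for the YAML schema).

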