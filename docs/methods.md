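# Methods

## Model

The package treats molecular kinetics as a Markov jump process on
conformational microstates.  Given per-frame microstate labels, transition
pairs (s_t, s_{t+τ}) are counted at a lag of τ frames (sliding window by
default; a strided mode is available when strictly independent counts are
wanted).  Counting never crosses trajectory boundaries.  The count matrix
is restricted to its largest strongly connected component — "largest" by
number of states, ties broken by total counts — because row normalisation
is only meaningful on an ergodic set; states dropped here (empty k-means
clusters, one-way sinks visited a handful of times) are retained in the
active-set mapping for reporting.  This trimming is why a 1,000-cluster
discretisation typically yields a slightly smaller active MSM.

Two estimators are provided:

* **row normalisation** (default): T_ij = c_ij / Σ_j c_ij, with π from the
  leading left eigenvector.  Fast and unbiased, but detailed balance holds
  only asymptotically.
* **reversible maximum likelihood**: fixed-point iteration on the
  symmetric variables x_ij of the detailed-balance-constrained likelihood,
  converged when T changes by < 1e-10 in max-abs norm.  π is the
  normalised row sum of x.  PCCA+ and transition path theory consume a
  real spectrum and exact detailed balance, so they default to this
  estimator's output.

Eigenvalues are sorted by magnitude with the eigenvalue nearest 1 pinned
first (other unit-modulus eigenvalues — periodic or complex pairs of
non-reversible matrices — must not displace the stationary process).  For
reversible matrices the spectrum is computed on the π-symmetrised matrix
D^{1/2} T D^{-1/2}, which guarantees real eigenvalues.  Complex
eigenvalues elsewhere are used by magnitude with a logged warning.

Implied timescales are t_i = −τ / ln λ_i in physical units; non-positive
eigenvalues yield NaN (flagged, never an exception) since the formula has
no real value there.  Markovianity is judged by the flatness of t_i(τ)
across lags, with a Chapman–Kolmogorov spot-check (‖T(τ)² − T(2τ)‖_F)
available as a second opinion.

Free-energy landscapes are −ln of π-reweighted 2D histograms on PC planes:
each frame carries weight π(state)/n_frames(state), F is shifted so the
occupied-bin minimum is 0, and empty bins are masked rather than zeroed.
Units are kT throughout (temperature never enters explicitly).

## Coarse-graining and pathways

PCCA+ uses the simplex structure of the first n right eigenvectors of a
reversible T: an inner-simplex vertex search (take the row of maximal
norm, deflate, repeat with Gram–Schmidt orthogonalisation) finds n
microstates spanning the simplex; memberships are the linear transform of
the eigenvector matrix by the inverse of the vertex rows, clipped at 0 and
renormalised row-wise.  The first eigenvector column is set to the
constant vector explicitly, which also handles exactly decoupled blocks
(degenerate unit eigenvalues).  Crisp assignments are row argmaxes;
"crispness" (the smallest row maximum) is reported so a poor lumping is
visible.  Coarse transition probabilities are the standard projection
χᵀ diag(π) T χ, row-normalised.

Transition path theory: the forward committor solves its linear system on
the intermediate states with q⁺ = 0 on the source and 1 on the sink; the
backward committor uses the time-reversed chain (1 − q⁺ for reversible
input).  Gross flux f_ij = π_i q⁻_i T_ij q⁺_j with flux out of the sink
and into the source removed; net flux is max(f − fᵀ, 0).  Pathways are
extracted greedily by repeatedly finding the widest (maximum-bottleneck)
source→sink path through the net-flux network with a max-min Dijkstra
variant and subtracting its bottleneck flux — the conventional reading of
"highest-flux pathways".

Representative structures of a microstate are the frames nearest (k-d
tree, Euclidean in PC space) to the state's mean PC vector, ties to the
lowest frame index.  Long trajectories are reconstructed by sampling the
chain from T (10,000 jumps at a 10 ns lag = 100 µs under the default
protocol) and mapping each state to its representative frame.

Robustness uses a whole-trajectory bootstrap: resample trajectories with
replacement (default 5 datasets × 300 trajectories), rebuild MSM + PCCA+
identically, align macrostate labels across datasets by Hungarian
assignment on π-weighted crisp membership overlap in the shared microstate
space, and report the maximum pairwise total-variation distance of the
matched population vectors.  Matching on membership overlap (rather than
on populations) keeps the alignment tied to which microstates constitute a
macrostate, so the dispersion is invariant to arbitrary label order.

## Featurization and discretisation

RMSD uses Kabsch superposition via a batched 3×3 SVD with the determinant
correction restricting to proper rotations; the deviation is computed on
the explicitly rotated coordinates because the usual
G_a + G_b − 2·trace shortcut cancels catastrophically near zero.
Superposition is the default (it removes irrelevant whole-complex
diffusion) and is switched off automatically for selections of fewer than
three atoms, where plain coordinate RMSD is the only defined choice.

Landmarks are true medoid frames, never averages: k-medoids++ seeding
followed by Voronoi iteration (move each medoid to the member minimising
total intra-cluster distance), best of 5 restarts, ties to the lowest
frame index.  Exact medoid search over millions of frames is quadratic and
pointless; the search runs on a uniform subsample (default 10,000 frames)
and all frames are then featurized against the chosen medoids.

PCA and k-means are scikit-learn underneath, wrapped to fix conventions:
component signs are normalised (largest-magnitude loading positive),
k-means uses full-batch Lloyd with k-means++ and a fixed seed for
determinism (mini-batch available for very large frame counts), and
distances in PC space are unscaled Euclidean.

## Synthetic data

The generators emulate the statistical structure of a steered-seeded
membrane-receptor binding study; their defaults are the study conditions:

* **Protocol bookkeeping** (`StudyManifest`): 379 + 335 seeds across two
  docking models, 100 ns production per seed sampled every 10 ps
  (71.4 µs, 7,140,000 frames), a steered grid of 15,000 structures from
  2 × 5 pulls of 50 ns, and a 100 µs reconstruction (10,000 × 10 ns).
  The grid is parameterised as 1,500 retained structures per pull so the
  totals are internally consistent.
* **Discrete chains**: exact row-stochastic ground truth for estimator
  tests; sampling is vectorised across trajectories and bit-reproducible
  per (spec, seed), one named generator per operation.
* **Brownian dynamics**: overdamped Euler–Maruyama,
  x' = x − ∇U dt + √(2D dt) ξ, on bounded built-in 2D potentials (flat,
  harmonic, double-well with wells at x = ±1, triple-well with wells at
  x = −2, 0, +2 and barriers ≈ 0.95 at the default scale).  A trajectory
  leaving the declared box raises an error advising a smaller timestep.
  The stationary density is ∝ exp(−U/D), so D tunes hopping rates; the
  defaults used in tests (D = 0.45, dt = 0.01) give well-resolved
  metastability with transitions every few hundred steps.
* **Gated receptor–ligand toy**: a ring of pseudo-atoms (radius 10 Å) in
  the z = 0 plane whose wall is an impenetrable cylinder except at a gate
  — two ring positions whose separation follows a two-state telegraph
  process (closed 4 Å / open 12 Å, switch probability 0.005 per step,
  Gaussian jitter 0.3 Å), chosen as the simplest process reproducing a
  bimodal gap-width histogram.  The ligand diffuses (per-step noise
  0.8 Å) with a Gaussian attractive well (depth 3, width 3 Å) at the
  internal site and may cross the wall only through the gate aperture
  while the instantaneous separation exceeds 7 Å; with the gate closed,
  entry is impossible by construction.  While the ligand is inside, the
  gate is held open — hence bound-state gap widths concentrate near the
  open width, mirroring the narrower, wider-than-closed bound-state gap
  distributions seen in lateral-access receptors.  "Bound" means distance
  to the internal site below the ring radius.  Coordinates are labelled Å
  so the same observables code serves real structures.
* **Steered seeding emulator**: linear interpolation of the ligand from
  bound to unbound pose on a dense grid (default 15,000), sampled
  uniformly at random without replacement (the real spreading protocol is
  unknown; uniform is the natural uninformative choice), with optional
  Gaussian jitter.  No pulling forces are simulated — only the seeding
  statistics matter downstream.

What the toys do **not** emulate: real force fields, solvent and membrane
friction, anisotropic gate mechanics, or the dimensionality of true
conformational spaces.  Passing tests therefore demonstrate correctness of
the inference machinery on systems whose answers are known — not that any
particular receptor's kinetics are converged at a given sampling depth.

## Numerical choices and edge rules

* Tolerances: row-stochasticity 1e-10, πT = π and detailed balance 1e-8,
  PCCA+ membership row sums 1e-8 with negatives clipped at −1e-10,
  committor/flux conservation 1e-8, reversible-MLE convergence 1e-10.
* Ties: medoid updates and representative frames break to the lowest
  frame index; eigenvector matching in the non-reversible branch is
  greedy nearest-eigenvalue.
* Moving averages are trailing, with the first window−1 entries averaged
  over the available prefix; centered alignment was rejected to keep the
  series causal.
* Selections resolving to zero atoms raise instead of returning an empty
  list, to catch typos in residue numbers early.
* Degenerate inputs: identity transition matrices reconstruct constant
  trajectories; a condition class with no frames omits its histogram with
  a warning; disconnected TPT source/sink warns and reports zero flux.

## Problem sizes in tests and the acceptance script

Estimator checks use 10⁶ sampled transitions (100 trajectories × 10,000
steps), where sampling error on a 3-state matrix is comfortably below the
0.01 entrywise bound.  The end-to-end well-recovery run uses 12 × 6,000
triple-well steps, 30 landmarks from a 400-frame pool, 2 PCs and 50
microstates at lag 20 — small enough to run in seconds, large enough that
PCCA+ recovery of the true wells (≥95% of frames) is far from chance.
Closed-gate exclusion is checked over 10⁶ steps; reconstruction
ergodicity over 10⁶ jumps of a 5-state chain (total-variation < 0.01).
These sizes are the package's reference benchmarks; all scale linearly if
larger runs are wanted.

## Known limitations

* PCCA+ uses the inner-simplex transform without the subsequent
  feasibility optimisation of the full algorithm; on well-separated
  metastable systems the difference is negligible, but memberships can be
  less crisp near degenerate spectra.
* The reversible estimator assumes the trimmed count graph is connected;
  it does not implement Bayesian uncertainty (no posterior sampling).
* Implied timescales from non-reversible matrices with strongly complex
  spectra are magnitude-based approximations and are flagged as such.
* The binary coordinate archive stores no topology; PDB remains the
  interchange format for anything with atom identities.
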