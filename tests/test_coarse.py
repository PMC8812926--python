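"""PCCA+ lumping, representatives, reconstruction, TPT and bootstrap."""

import numpy as np
import pytest

from lama.exceptions import ValidationError
from lama.coarse import (
    bootstrap_msm,
    pcca_plus,
    reconstruct_trajectory,
    representative_frame,
    tpt,
)
from lama.msm import MarkovStateModel, MSMResults
from lama.reduce_cluster import MicrostateAssignment, cluster_microstates
from lama.toymodel import DiscreteChainSpec, sample_discrete_chain, stationary_distribution


def _block_T():
    T = np.zeros((4, 4))
    T[:2, :2] = [[0.9, 0.1], [0.1, 0.9]]
    T[2:, 2:] = [[0.8, 0.2], [0.2, 0.8]]
    return T


class TestPCCA:
    def test_uncoupled_blocks_resolved_crisply(self):
        res = MSMResults.from_transition_matrix(_block_T())
        macro = pcca_plus(res, 2)
        a = macro.assignments
        assert a[0] == a[1] and a[2] == a[3] and a[0] != a[2]
        assert np.abs(macro.memberships - np.round(macro.memberships)).max() < 1e-6

    def test_identity_lumping_when_n_equals_states(self):
        res = MSMResults.from_transition_matrix(_block_T())
        macro = pcca_plus(res, 4)
        assert np.allclose(macro.memberships, np.eye(4))

    def test_macrostate_populations_conserve_probability(self, metastable4_dtrajs):
        res = MarkovStateModel(metastable4_dtrajs, lag=1, reversible=True).fit()
        macro = pcca_plus(res, 2)
        assert macro.populations.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.abs(macro.memberships.sum(axis=1) - 1).max() < 1e-8

    def test_metastable_chain_lumped_by_kinetic_blocks(self, metastable4_dtrajs):
        res = MarkovStateModel(metastable4_dtrajs, lag=1, reversible=True).fit()
        macro = pcca_plus(res, 2)
        a = macro.assignments
        assert a[0] == a[1] and a[2] == a[3] and a[0] != a[2]

    def test_coarse_transition_matrix_is_stochastic(self, metastable4_dtrajs):
        res = MarkovStateModel(metastable4_dtrajs, lag=1, reversible=True).fit()
        Tc = pcca_plus(res, 2).coarse_transition_matrix()
        assert np.allclose(Tc.sum(axis=1), 1.0)
        assert Tc[0, 0] > 0.9   # metastable blocks rarely interconvert

    def test_complex_spectrum_advises_reversible_estimation(self):
        T = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        res = MSMResults.from_transition_matrix(T)
        with pytest.raises(ValidationError, match="reversible"):
            pcca_plus(res, 2)


class TestRepresentativeFrame:
    def _assignment(self, labels):
        labels = np.asarray(labels)
        n = labels.size
        return MicrostateAssignment(
            centers=np.zeros((labels.max() + 1, 2)),
            labels=labels,
            traj_idx=np.zeros(n, dtype=np.intp),
            frame_idx=np.arange(n, dtype=np.intp),
            inertia=0.0,
        )

    def test_singleton_state_returns_its_frame(self):
        pcs = np.array([[0.0, 0], [5, 5], [9, 9]])
        asg = self._assignment([0, 1, 0])
        assert representative_frame(asg, pcs, 1) == 1

    def test_collinear_points_pick_median(self):
        pcs = np.array([[float(i), 0.0] for i in range(5)])
        asg = self._assignment([0] * 5)
        assert representative_frame(asg, pcs, 0) == 2

    def test_agrees_with_linear_scan_oracle(self):
        rng = np.random.default_rng(0)
        pcs = rng.normal(size=(1000, 3))
        labels = rng.integers(0, 4, size=1000)
        asg = self._assignment(labels)
        for state in range(4):
            members = np.flatnonzero(labels == state)
            center = pcs[members].mean(axis=0)
            oracle = members[np.argmin(np.linalg.norm(pcs[members] - center, axis=1))]
            assert representative_frame(asg, pcs, state) == oracle

    def test_empty_state_errors(self):
        asg = self._assignment([0, 0])
        with pytest.raises(ValidationError):
            representative_frame(asg, np.zeros((2, 2)), 1)


class TestReconstruction:
    def test_identity_matrix_gives_constant_trajectory(self):
        res = MSMResults.from_transition_matrix(np.eye(3))
        rec = reconstruct_trajectory(res, 1, 100, seed=0)
        assert np.all(rec.microstates == 1)

    def test_declared_duration_is_steps_times_lag(self):
        res = MSMResults.from_transition_matrix(
            np.array([[0.9, 0.1], [0.1, 0.9]]), lag_time=10.0, time_unit="ns")
        rec = reconstruct_trajectory(res, 0, 10_000, seed=0)
        assert rec.duration == pytest.approx(100_000.0)   # ns: 100 us

    def test_two_state_symmetric_occupancy(self):
        res = MSMResults.from_transition_matrix(np.array([[0.9, 0.1], [0.1, 0.9]]))
        rec = reconstruct_trajectory(res, 0, 1_000_000, seed=1)
        frac = np.mean(rec.microstates == 0)
        assert abs(frac - 0.5) < 0.002 + 3 * np.sqrt(0.25 / 100_000)

    def test_successive_states_connected_by_nonzero_T(self):
        T = np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
        res = MSMResults.from_transition_matrix(T)
        rec = reconstruct_trajectory(res, 0, 2000, seed=2)
        s = rec.microstates
        assert np.all(T[s[:-1], s[1:]] > 0)

    def test_start_outside_active_set_errors(self):
        res = MSMResults.from_transition_matrix(np.eye(2))
        with pytest.raises(ValidationError):
            reconstruct_trajectory(res, 5, 10)


class TestTPT:
    def test_symmetric_three_state_committor(self):
        T = np.array([[0.8, 0.2, 0.0], [0.2, 0.6, 0.2], [0.0, 0.2, 0.8]])
        res = MSMResults.from_transition_matrix(T)
        r = tpt(res, [0], [2])
        assert np.allclose(r.committor_forward, [0.0, 0.5, 1.0], atol=1e-10)

    def test_birth_death_committor_matches_closed_form(self):
        # 1D chain with asymmetric hop rates; gambler's-ruin closed form
        n = 7
        p, q = 0.3, 0.2
        T = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                T[i, i - 1] = q
            if i < n - 1:
                T[i, i + 1] = p
            T[i, i] = 1.0 - T[i].sum()
        res = MSMResults.from_transition_matrix(T)
        r = tpt(res, [0], [n - 1])
        ratio = q / p
        weights = np.array([ratio**j for j in range(n - 1)])
        closed = np.array(
            [weights[:i].sum() for i in range(n)]) / weights.sum()
        assert np.abs(r.committor_forward - closed).max() < 1e-8

    def test_flux_conservation_at_intermediate_nodes(self, metastable4_dtrajs):
        res = MarkovStateModel(metastable4_dtrajs, lag=1, reversible=True).fit()
        r = tpt(res, [0], [3])
        f = r.gross_flux
        inter = [s for s in range(res.n_states) if s not in (0, 3)]
        for i in inter:
            assert f[:, i].sum() == pytest.approx(f[i, :].sum(), abs=1e-8)

    def test_backward_committor_complements_forward_for_reversible(self,
                                                                   metastable4_dtrajs):
        res = MarkovStateModel(metastable4_dtrajs, lag=1, reversible=True).fit()
        r = tpt(res, [0], [3])
        assert np.abs(r.committor_forward + r.committor_backward - 1.0).max() < 1e-8

    def test_total_flux_invariant_under_set_reversal(self, metastable4_dtrajs):
        res = MarkovStateModel(metastable4_dtrajs, lag=1, reversible=True).fit()
        fwd = tpt(res, [0, 1], [2, 3]).total_flux
        bwd = tpt(res, [2, 3], [0, 1]).total_flux
        assert fwd == pytest.approx(bwd, rel=1e-8)

    def test_pathway_fluxes_bounded_by_total(self, metastable4_dtrajs):
        res = MarkovStateModel(metastable4_dtrajs, lag=1, reversible=True).fit()
        r = tpt(res, [0], [3])
        assert sum(f for _, f in r.pathways) <= r.total_flux + 1e-10
        assert r.pathways[0][0][0] == 0 and r.pathways[0][0][-1] == 3

    def test_overlapping_sets_error(self):
        res = MSMResults.from_transition_matrix(np.full((3, 3), 1 / 3))
        with pytest.raises(ValidationError):
            tpt(res, [0, 1], [1, 2])


class TestBootstrap:
    def test_degenerate_population_gives_zero_dispersion(self, metastable4_dtrajs):
        same = [metastable4_dtrajs[0].copy() for _ in range(10)]
        br = bootstrap_msm(same, lag=1, n_macrostates=2, n_datasets=5,
                           resample_size=30, seed=0)
        assert br.dispersion == pytest.approx(0.0, abs=1e-12)

    def test_heterogeneous_data_has_finite_reported_dispersion(self,
                                                               metastable4_dtrajs):
        br = bootstrap_msm(metastable4_dtrajs, lag=1, n_macrostates=2,
                           n_datasets=5, resample_size=80, seed=1)
        assert np.isfinite(br.dispersion) and 0 <= br.dispersion < 1

    def test_default_protocol_five_datasets_of_300(self):
        import inspect
        sig = inspect.signature(bootstrap_msm)
        assert sig.parameters["n_datasets"].default == 5
        assert sig.parameters["resample_size"].default == 300

    def test_fixed_seed_reproduces_resample_indices(self, metastable4_dtrajs):
        b1 = bootstrap_msm(metastable4_dtrajs, 1, 2, 3, 20, seed=4)
        b2 = bootstrap_msm(metastable4_dtrajs, 1, 2, 3, 20, seed=4)
        assert np.array_equal(b1.resample_indices, b2.resample_indices)

    def test_label_matching_aligns_kinetic_blocks(self, metastable4_dtrajs):
        # arbitrary PCCA+ label order must be undone by the Hungarian
        # matching: across datasets, the macrostate holding microstate 0
        # must land in the same matched column
        br = bootstrap_msm(metastable4_dtrajs, lag=1, n_macrostates=2,
                           n_datasets=4, resample_size=60, seed=2)
        ref = br.models[0]
        ref_col = ref.assignments[np.searchsorted(ref.active_set, 0)]
        block_pop = ref.populations[ref_col]
        for model, row in zip(br.models[1:], br.populations[1:]):
            col = model.assignments[np.searchsorted(model.active_set, 0)]
            # matched population of the block containing microstate 0
            assert abs(row[ref_col] - model.populations[col]) < 1e-12
        assert 0.3 < block_pop < 0.7

    def test_too_few_datasets_error(self, metastable4_dtrajs):
        with pytest.raises(ValidationError):
            bootstrap_msm(metastable4_dtrajs, 1, 2, n_datasets=1)


class TestEndToEndWellRecovery:
    def test_three_well_pipeline_recovers_wells(self, triple_well_ensemble):
        """featurize → PCA → k-means → MSM → PCCA+ groups ≥95% of frames by well."""
        from scipy.optimize import linear_sum_assignment

        from lama.featurize import featurize_ensemble, select_landmarks
        from lama.reduce_cluster import fit_pca

        ens = triple_well_ensemble
        x = np.concatenate([c[:, 0, 0] for c in ens.coords])
        wells = np.array([-2.0, 0.0, 2.0])
        truth = np.argmin(np.abs(x[:, None] - wells[None]), axis=1)

        lm = select_landmarks(ens, n_landmarks=30, max_frames_for_medoid=400, seed=0)
        fm = featurize_ensemble(ens, lm)
        pca = fit_pca(fm, n_components=2)
        pcs = pca.transform(fm)
        asg = cluster_microstates(pcs, k=50, seed=0, n_init=3,
                                  traj_idx=fm.traj_idx, frame_idx=fm.frame_idx)
        res = MarkovStateModel(asg.discrete_trajectories(), lag=20,
                               reversible=True).fit()
        macro = pcca_plus(res, 3)
        full2macro = np.full(asg.k, -1)
        full2macro[macro.active_set] = macro.assignments
        mlab = full2macro[asg.labels]
        conf = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                conf[i, j] = np.sum((truth == i) & (mlab == j))
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / truth.size >= 0.95
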