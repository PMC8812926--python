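"""Counting, ergodic trimming, estimators, spectra, timescales, landscapes."""

import numpy as np
import pytest

from lama.exceptions import LamaError, ValidationError
from lama.msm import (
    CountMatrix,
    MarkovStateModel,
    MSMResults,
    ck_test,
    count_transitions,
    estimate_T,
    frame_weights,
    implied_timescales,
    project_free_energy,
    trim_to_ergodic,
)


class TestCounting:
    def test_sliding_counts_enumerated_example(self):
        c = count_transitions([np.array([0, 1, 0, 1])], lag_frames=1)
        assert c.matrix.tolist() == [[0, 2], [1, 0]]

    def test_counting_never_crosses_trajectory_boundaries(self):
        c = count_transitions([np.array([0, 0]), np.array([1, 1])], lag_frames=1)
        assert c.matrix.tolist() == [[1, 0], [0, 1]]

    def test_lag_two_pairs(self):
        c = count_transitions([np.array([0, 1, 2, 3])], lag_frames=2)
        expected = np.zeros((4, 4))
        expected[0, 2] = expected[1, 3] = 1
        assert np.array_equal(c.matrix, expected)

    def test_strided_mode_counts_independent_pairs(self):
        c = count_transitions([np.array([0, 1, 0, 1, 0])], lag_frames=2,
                              mode="strided")
        assert c.matrix[0, 0] == 2 and c.matrix.sum() == 2

    def test_all_sequences_shorter_than_lag_errors(self):
        with pytest.raises(ValidationError, match="lag"):
            count_transitions([np.array([0, 1])], lag_frames=5)


class TestErgodicTrim:
    def test_fully_connected_keeps_identity_mapping(self):
        C = CountMatrix(np.ones((3, 3)), 1)
        trimmed, active = trim_to_ergodic(C)
        assert active.tolist() == [0, 1, 2]
        assert np.array_equal(trimmed.matrix, C.matrix)

    def test_block_diagonal_keeps_larger_block(self):
        M = np.zeros((5, 5))
        M[:3, :3] = 5.0
        M[3:, 3:] = 1.0
        trimmed, active = trim_to_ergodic(CountMatrix(M, 1))
        assert active.tolist() == [0, 1, 2]

    def test_one_way_sink_is_excluded(self):
        # 0 <-> 1, both leak into sink 2 which never returns
        M = np.array([[5.0, 5, 1], [5, 5, 1], [0, 0, 0]])
        trimmed, active = trim_to_ergodic(CountMatrix(M, 1))
        assert active.tolist() == [0, 1]
        # oracle: strongly connected components by Tarjan via networkx
        import networkx as nx
        g = nx.from_numpy_array(M > 0, create_using=nx.DiGraph)
        scc = max(nx.strongly_connected_components(g), key=len)
        assert sorted(scc) == active.tolist()


class TestEstimators:
    def test_symmetric_counts_normalise_exactly(self):
        T, pi = estimate_T(CountMatrix(np.array([[8.0, 2], [2, 8]]), 1))
        assert np.allclose(T, [[0.8, 0.2], [0.2, 0.8]])
        assert np.allclose(pi, [0.5, 0.5])

    def test_periodic_chain_spectrum(self):
        res = MSMResults.from_transition_matrix(np.array([[0.0, 1], [1, 0]]))
        lams = sorted(np.real(res.eigenvalues))
        assert lams == pytest.approx([-1.0, 1.0])

    def test_million_transition_recovery_below_point_zero_one(
            self, three_state_T, three_state_dtrajs):
        res = MarkovStateModel(three_state_dtrajs, lag=1).fit()
        assert np.abs(res.transition_matrix - three_state_T).max() < 0.01

    def test_reversible_estimator_satisfies_detailed_balance(
            self, three_state_dtrajs):
        res = MarkovStateModel(three_state_dtrajs, lag=1, reversible=True).fit()
        flux = res.stationary_distribution[:, None] * res.transition_matrix
        assert np.abs(flux - flux.T).max() < 1e-8

    def test_every_msm_satisfies_spectral_contracts(self, metastable4_dtrajs):
        for reversible in (False, True):
            res = MarkovStateModel(metastable4_dtrajs, lag=2,
                                   reversible=reversible).fit()
            T, pi = res.transition_matrix, res.stationary_distribution
            assert np.abs(T.sum(axis=1) - 1).max() < 1e-10
            assert abs(res.eigenvalues[0] - 1) < 1e-8
            assert np.abs(res.eigenvalues).max() < 1 + 1e-10
            assert np.abs(pi @ T - pi).max() < 1e-8

    def test_zero_row_is_an_internal_error(self):
        with pytest.raises(LamaError, match="empty row"):
            estimate_T(CountMatrix(np.array([[1.0, 1], [0, 0]]), 1))


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        res = MSMResults.from_transition_matrix(
            np.array([[0.8, 0.2], [0.2, 0.8]]), lag_time=10.0, time_unit="ns")
        assert res.timescales(1)[0] == pytest.approx(-10 / np.log(0.6), rel=1e-12)

    def test_markovian_data_gives_flat_timescales(self, metastable4_dtrajs):
        its = implied_timescales(metastable4_dtrajs, [1, 2, 5, 10], n_processes=1)
        t2 = its.timescales[:, 0]
        assert np.all(np.isfinite(t2))
        assert (t2.max() - t2.min()) / t2.mean() < 0.10

    def test_timescale_recovery_within_15_percent(self, metastable4_T,
                                                  metastable4_dtrajs):
        lams = np.sort(np.real(np.linalg.eigvals(metastable4_T)))[::-1]
        t2_true = -1.0 / np.log(lams[1])
        res = MarkovStateModel(metastable4_dtrajs, lag=1).fit()
        t2 = res.timescales(1)[0]
        assert abs(t2 - t2_true) / t2_true < 0.15

    def test_timescale_diverges_as_lambda_approaches_one(self):
        ts = []
        for lam in (0.9, 0.99, 0.999):
            T = np.array([[(1 + lam) / 2, (1 - lam) / 2],
                          [(1 - lam) / 2, (1 + lam) / 2]])
            ts.append(MSMResults.from_transition_matrix(T).timescales(1)[0])
        assert ts[0] < ts[1] < ts[2]

    def test_nonpositive_eigenvalue_reported_as_nan_not_raise(self):
        res = MSMResults.from_transition_matrix(np.array([[0.1, 0.9], [0.9, 0.1]]))
        assert np.isnan(res.timescales(1)[0])

    def test_unsorted_lags_rejected(self, metastable4_dtrajs):
        with pytest.raises(ValidationError):
            implied_timescales(metastable4_dtrajs, [5, 1])


class TestChapmanKolmogorov:
    def test_markovian_synthetic_data_passes_spot_check(self, three_state_dtrajs):
        assert ck_test(three_state_dtrajs, lag=2) < 0.02


class TestFreeEnergy:
    def _series(self, pts):
        return np.asarray(pts, dtype=float)

    def test_single_occupied_bin_is_zero_rest_masked(self):
        pcs = np.zeros((10, 2))
        fel = project_free_energy(pcs, np.ones(10), n_bins=5)
        occupied = ~fel.free_energy.mask
        assert occupied.sum() == 1
        assert fel.free_energy.compressed()[0] == pytest.approx(0.0)

    def test_probability_ratio_gives_ln4(self):
        pcs = np.array([[0.0, 0.0]] * 8 + [[1.0, 1.0]] * 2)
        fel = project_free_energy(pcs, np.ones(10), n_bins=2)
        vals = np.sort(fel.free_energy.compressed())
        assert vals[0] == pytest.approx(0.0)
        assert vals[1] == pytest.approx(np.log(4), abs=1e-12)

    def test_msm_reweighted_landscape_matches_long_run_histogram(self):
        """Two-well Brownian data: MSM-weighted −ln p vs direct histogram."""
        from lama.reduce_cluster import cluster_microstates
        from lama.toymodel import LangevinSpec, simulate_langevin

        spec = LangevinSpec("double-well", diffusion_coefficient=0.6,
                            timestep=0.01, n_steps=40_000, n_trajectories=4,
                            seed=9)
        ens = simulate_langevin(spec)
        pts = np.concatenate([c[:, 0, :2] for c in ens.coords])
        asg = cluster_microstates(pts, k=30, seed=0, n_init=3)
        # rebuild per-trajectory label sequences
        L = ens.coords[0].shape[0]
        dtrajs = [asg.labels[i * L:(i + 1) * L] for i in range(4)]
        res = MarkovStateModel(dtrajs, lag=10, reversible=True).fit()
        w = frame_weights(res, asg.labels)
        edges = [np.linspace(-2, 2, 13), np.linspace(-2.5, 2.5, 13)]
        Hw, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=edges, weights=w)
        Hd, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=edges)
        pw, pd = Hw / Hw.sum(), Hd / Hd.sum()
        # compare in well regions (bins holding the top half of direct mass)
        well = pd > np.quantile(pd[pd > 0], 0.75)
        dF = np.abs(-np.log(pw[well]) + np.log(pd[well]))
        assert dF.max() < 0.3

    def test_all_zero_weights_error(self):
        with pytest.raises(ValidationError):
            project_free_energy(np.zeros((5, 2)), np.zeros(5))


class TestFrameWeights:
    def test_weights_sum_to_one_on_fully_active_data(self, three_state_dtrajs):
        res = MarkovStateModel(three_state_dtrajs, lag=1).fit()
        labels = np.concatenate(three_state_dtrajs)
        w = frame_weights(res, labels)
        assert w.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(w >= 0)


def test_summary_reports_lag_and_estimator(three_state_dtrajs):
    res = MarkovStateModel(three_state_dtrajs, lag=1, frame_interval=10.0,
                           time_unit="ps", reversible=True).fit()
    text = res.summary()
    assert "10 ps" in text and "reversible" in text and "t_2" in text
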