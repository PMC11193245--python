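"""SVAR structure learner: encoding, acyclicity function, fitting, rules."""

from __future__ import annotations

import numpy as np
import pytest

from modulelearn import (
    SVARModel,
    encode_binary_panel,
    fit_dynotears,
    h_acyclicity,
    simulate_svar,
    structural_hamming_distance,
    svar_to_rules,
)
from modulelearn.datatypes import START_ID, STOP_ID, dataset_from_id_lists
from conftest import A, B, C


def has_cycle(adj: np.ndarray) -> bool:
    """Oracle: depth-first search for a directed cycle on a 0/1 adjacency."""
    n = adj.shape[0]
    color = [0] * n  # 0 white, 1 on stack, 2 done

    def dfs(u: int) -> bool:
        color[u] = 1
        for v in range(n):
            if adj[u, v]:
                if color[v] == 1 or (color[v] == 0 and dfs(v)):
                    return True
        color[u] = 2
        return False

    return any(color[u] == 0 and dfs(u) for u in range(n))


class TestEncodeBinaryPanel:
    def test_window_count_is_length_minus_lag(self):
        ds = dataset_from_id_lists([[START_ID, A, STOP_ID]])
        dm = encode_binary_panel(ds, p=1)
        assert dm.M == 2  # (START->A), (A->STOP)

    def test_pooled_windows_never_cross_patients(self):
        ds = dataset_from_id_lists(
            [
                [START_ID, A, B, STOP_ID],      # T=4
                [START_ID, A, C, STOP_ID],      # T=4
                [START_ID, B, STOP_ID],         # T=3
            ]
        )
        dm = encode_binary_panel(ds, p=1)
        assert dm.M == 3 + 3 + 2

    def test_rows_are_one_hot(self):
        ds = dataset_from_id_lists([[START_ID, A, B, A, STOP_ID], [START_ID, C, STOP_ID]])
        dm = encode_binary_panel(ds, p=2)
        assert np.all(dm.X.sum(axis=1) == 1)
        assert np.all(dm.Y.sum(axis=1) == dm.p)
        assert set(np.unique(dm.X)) <= {0.0, 1.0}

    def test_top_k_keeps_most_frequent_plus_sentinels(self):
        ds = dataset_from_id_lists([[START_ID, A, A, B, STOP_ID], [START_ID, A, C, STOP_ID]])
        dm = encode_binary_panel(ds, top_k=1)
        assert set(dm.concepts) == {START_ID, STOP_ID, A}

    def test_short_sequences_skipped(self):
        ds = dataset_from_id_lists([[START_ID, STOP_ID], [START_ID, A, STOP_ID]])
        dm = encode_binary_panel(ds, p=2)
        assert dm.M == 1  # only the longer sequence yields a p=2 window


class TestAcyclicityFunction:
    def test_zero_matrix(self):
        assert h_acyclicity(np.zeros((4, 4))) == pytest.approx(0.0, abs=1e-12)

    def test_two_cycle_closed_form(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert h_acyclicity(W) == pytest.approx(2 * np.cosh(1.0) - 2, abs=1e-9)

    def test_strictly_upper_triangular_is_acyclic(self):
        rng = np.random.default_rng(3)
        W = np.triu(rng.normal(size=(5, 5)), k=1)
        assert h_acyclicity(W) < 1e-10

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            h_acyclicity(np.zeros((2, 3)))

    def test_agrees_with_cycle_detector_on_random_matrices(self):
        rng = np.random.default_rng(42)
        seen_cyclic = seen_acyclic = 0
        for _ in range(200):
            W = rng.normal(size=(4, 4)) * (rng.random((4, 4)) < 0.35)
            np.fill_diagonal(W, 0.0)
            cyc = has_cycle(np.abs(W) > 1e-8)
            if cyc:
                assert h_acyclicity(W) >= 1e-8
                seen_cyclic += 1
            else:
                assert h_acyclicity(W) < 1e-8
                seen_acyclic += 1
        assert seen_cyclic > 20 and seen_acyclic > 20


class TestFitDynotears:
    def test_null_model_yields_no_edges(self):
        dm, _ = simulate_svar(d=5, p=1, edge_prob=0.0, noise_sd=0.1, M=1000, seed=7)
        est = fit_dynotears(dm, lambda_w=0.1, lambda_a=0.1)
        assert np.all(np.abs(est.W) <= 0.3)
        assert np.all(np.abs(est.A) <= 0.3)

    def test_recovers_known_structure(self):
        dm, truth = simulate_svar(
            d=5, p=1, edge_prob=0.3, coef_range=(0.5, 1.0), noise_sd=0.1, M=2000, seed=1
        )
        est = fit_dynotears(dm, lambda_w=0.001, lambda_a=0.001, standardize=False)
        assert structural_hamming_distance(est, truth, threshold=0.3) <= 1

    def test_heavy_penalty_zeroes_everything(self):
        dm, _ = simulate_svar(d=4, p=1, edge_prob=0.4, noise_sd=0.1, M=500, seed=5)
        est = fit_dynotears(dm, lambda_w=50.0, lambda_a=50.0)
        assert np.all(est.W == 0.0)
        assert np.all(est.A == 0.0)

    def test_diagonal_of_w_forced_zero(self):
        dm, _ = simulate_svar(d=4, p=1, edge_prob=0.4, noise_sd=0.1, M=500, seed=6)
        est = fit_dynotears(dm)
        assert np.all(np.diag(est.W) == 0.0)

    def test_returned_w_is_near_acyclic(self):
        dm, _ = simulate_svar(d=5, p=1, edge_prob=0.4, noise_sd=0.1, M=1000, seed=8)
        est = fit_dynotears(dm, lambda_w=0.001, lambda_a=0.001, standardize=False)
        assert est.converged
        assert h_acyclicity(est.W * (np.abs(est.W) > 1e-6)) < 1e-6

    def test_deterministic(self):
        dm, _ = simulate_svar(d=4, p=1, edge_prob=0.3, noise_sd=0.1, M=800, seed=9)
        e1 = fit_dynotears(dm)
        e2 = fit_dynotears(dm)
        assert np.array_equal(e1.W, e2.W) and np.array_equal(e1.A, e2.A)

    def test_inner_objective_decreases_in_each_accepted_iteration(self):
        dm, _ = simulate_svar(d=5, p=1, edge_prob=0.3, noise_sd=0.1, M=1000, seed=11)
        est = fit_dynotears(dm, lambda_w=0.001, lambda_a=0.001, standardize=False)
        assert est.objective_history
        for step in est.objective_history:
            assert step["f_end"] <= step["f_start"] + 1e-12

    def test_permutation_equivariant(self):
        dm, _ = simulate_svar(d=4, p=1, edge_prob=0.3, noise_sd=0.1, M=800, seed=13)
        est = fit_dynotears(dm, lambda_w=0.001, lambda_a=0.001, standardize=False)
        rng = np.random.default_rng(0)
        perm = rng.permutation(dm.d)
        dm_p = type(dm)(X=dm.X[:, perm], Y=dm.Y[:, perm], p=dm.p,
                        concepts=[dm.concepts[i] for i in perm])
        est_p = fit_dynotears(dm_p, lambda_w=0.001, lambda_a=0.001, standardize=False)
        assert np.allclose(est_p.W, est.W[np.ix_(perm, perm)], atol=1e-4)
        assert np.allclose(est_p.A, est.A[np.ix_(perm, perm)], atol=1e-4)


class TestSvarToRules:
    def _model(self, W, A, p=1):
        return SVARModel(W=np.asarray(W, float), A=np.asarray(A, float), p=p)

    def test_single_inter_slice_entry(self):
        A_ = np.zeros((3, 3))
        A_[0, 2] = 0.9
        g = svar_to_rules(self._model(np.zeros((3, 3)), A_), concepts=[10, 11, 12])
        assert g.edge_set() == {(10, 12)}
        rule = g.edges[(10, 12)]
        assert rule.weight == pytest.approx(0.9)
        assert rule.provenance == "dynotears-inter"

    def test_everything_below_threshold_is_empty(self):
        g = svar_to_rules(
            self._model(np.full((3, 3), 0.2), np.full((3, 3), -0.25)),
            concepts=[10, 11, 12],
        )
        assert g.n_edges == 0

    def test_lags_collapse_keeping_max_magnitude(self):
        A_ = np.zeros((6, 3))
        A_[0, 1] = 0.5    # lag 1: 0 -> 1
        A_[3, 1] = -0.7   # lag 2: 0 -> 1
        g = svar_to_rules(self._model(np.zeros((3, 3)), A_, p=2), concepts=[10, 11, 12])
        assert g.edges[(10, 11)].weight == pytest.approx(0.7)

    def test_intra_slice_edges_carry_their_own_provenance(self):
        W = np.zeros((3, 3))
        W[1, 2] = 0.8
        g = svar_to_rules(self._model(W, np.zeros((3, 3))), concepts=[10, 11, 12])
        assert g.edges[(11, 12)].provenance == "dynotears-intra"

    def test_sentinel_impossible_edges_skipped(self):
        A_ = np.zeros((3, 3))
        A_[2, 0] = 0.9  # into START: structurally impossible
        A_[1, 2] = 0.9  # out of STOP: structurally impossible
        g = svar_to_rules(
            self._model(np.zeros((3, 3)), A_), concepts=[START_ID, STOP_ID, 12]
        )
        assert g.n_edges == 0
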