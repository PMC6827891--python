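"""Simulator correctness and benchmark/scenario generators."""

import numpy as np
import pytest
from scipy.linalg import expm

from drynet.network import motif_census
from drynet.grn import GRN
from drynet.preprocess import hermite_interpolate
from drynet.synthetic import (
    SimulationSpec,
    evaluate_edge_recovery,
    make_benchmark_spec,
    make_recovery_spec,
    make_resistance_scenario,
    pcc_baseline,
    random_network_ensemble,
    simulate_timecourse,
)
from drynet.patterns import response_scores


class TestSimulator:
    def test_zero_dynamics_stay_at_initial_state(self):
        spec = SimulationSpec(A=np.zeros((3, 3)), b=np.zeros(3),
                              x0=np.array([1.0, 2.0, 3.0]))
        tcm = simulate_timecourse(spec, max_step=0.05)
        np.testing.assert_allclose(tcm.values, np.tile([[1], [2], [3.0]], 5))

    def test_pure_decay_matches_matrix_exponential(self):
        A = -0.1 * np.eye(3)
        x0 = np.array([10.0, 20.0, 30.0])
        spec = SimulationSpec(A=A, b=np.zeros(3), x0=x0)
        tcm = simulate_timecourse(spec)
        for j, t in enumerate(tcm.times):
            np.testing.assert_allclose(tcm.values[:, j], expm(A * t) @ x0,
                                       rtol=1e-6)

    def test_general_linear_system_matches_closed_form(self):
        A = np.array([[-0.2, 0.1], [0.05, -0.3]])
        b = np.array([0.5, 1.0])
        x0 = np.array([5.0, 8.0])
        spec = SimulationSpec(A=A, b=b, x0=x0)
        tcm = simulate_timecourse(spec)
        for j, t in enumerate(tcm.times):
            E = expm(A * t)
            xt = E @ x0 + np.linalg.solve(A, (E - np.eye(2)) @ b)
            np.testing.assert_allclose(tcm.values[:, j], xt, rtol=1e-6)

    def test_default_sampling_times(self):
        spec = SimulationSpec(A=np.zeros((2, 2)), b=np.zeros(2),
                              x0=np.ones(2))
        np.testing.assert_array_equal(spec.sample_times, [0, 6, 12, 24, 48])

    def test_divergence_raises_naming_spec(self):
        spec = SimulationSpec(A=np.array([[1.0, 0], [0, 1.0]]),
                              b=np.zeros(2), x0=np.array([10.0, 10.0]),
                              seed=77)
        with pytest.raises(FloatingPointError, match="77"):
            simulate_timecourse(spec, max_step=0.05)

    def test_noise_reproducible_under_seed(self):
        spec = SimulationSpec(A=-0.1 * np.eye(2), b=np.zeros(2),
                              x0=np.array([10.0, 20.0]), noise_sd=0.1, seed=3)
        t1 = simulate_timecourse(spec, max_step=0.05)
        t2 = simulate_timecourse(spec, max_step=0.05)
        np.testing.assert_array_equal(t1.values, t2.values)


class TestBenchmarkSpec:
    def test_contains_positive_and_negative_feedback(self):
        for seed in range(3):
            spec = make_benchmark_spec(seed)
            grn = GRN(spec.gene_ids, spec.A - np.diag(np.diag(spec.A)),
                      spec.b)
            census = motif_census(grn)
            assert census.counts["PF"] >= 1 and census.counts["NF"] >= 1

    def test_degradation_rate_on_diagonal(self):
        spec = make_benchmark_spec(0)
        np.testing.assert_allclose(np.diag(spec.A), -0.1)

    def test_fixed_seed_reproducible(self):
        s1, s2 = make_benchmark_spec(5), make_benchmark_spec(5)
        np.testing.assert_array_equal(s1.A, s2.A)
        np.testing.assert_array_equal(s1.x0, s2.x0)

    def test_trajectories_positive_and_bounded(self):
        spec = make_benchmark_spec(2)
        tcm = simulate_timecourse(spec)
        assert tcm.values.min() > 0 and tcm.values.max() < 5e3


class TestEnsemble:
    def test_requested_count_and_reproducibility(self):
        e1 = random_network_ensemble(n=4, seed=9)
        e2 = random_network_ensemble(n=4, seed=9)
        assert len(e1) == 4
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.A, b.A)

    def test_zero_density_gives_diagonal_only_dynamics(self):
        specs = random_network_ensemble(n=2, edge_density=0.0, seed=1)
        for s in specs:
            off = s.A - np.diag(np.diag(s.A))
            assert not off.any()

    def test_all_networks_stable(self):
        for s in random_network_ensemble(n=5, seed=2):
            assert np.max(np.real(np.linalg.eigvals(s.A))) < 0


class TestScenario:
    def test_no_extra_edges_gives_identical_arms(self):
        scen = make_resistance_scenario(0, n_extra_edges=0)
        np.testing.assert_array_equal(scen.sensitive.A, scen.resistant.A)

    def test_planted_edges_absent_from_sensitive_arm(self):
        scen = make_resistance_scenario(1)
        genes = scen.sensitive.gene_ids
        for src, tgt in scen.planted_edges:
            i, j = genes.index(tgt), genes.index(src)
            assert scen.sensitive.A[i, j] == 0
            assert scen.resistant.A[i, j] != 0

    def test_adaptive_response_higher_in_resistant_arm(self):
        # per run, the planted genes' mean adaptive score must be higher
        # in the resistant arm; asserted in >= 90% of seeded runs
        wins = 0
        n = 20
        for seed in range(n):
            scen = make_resistance_scenario(seed)
            sens = simulate_timecourse(scen.sensitive)
            res = simulate_timecourse(scen.resistant)
            sa_s, sa_r = [], []
            for g in scen.planted_genes:
                gi = sens.gene_ids.index(g)
                sa_s.append(response_scores(sens.values[gi], sens.times)[1])
                sa_r.append(response_scores(res.values[gi], res.times)[1])
            wins += np.mean(sa_r) > np.mean(sa_s)
        assert wins >= 0.9 * n

    def test_reproducible(self):
        a, b = make_resistance_scenario(4), make_resistance_scenario(4)
        np.testing.assert_array_equal(a.resistant.A, b.resistant.A)


class TestBaselinesAndScoring:
    def test_pcc_proportional_and_anticorrelated_are_one(self):
        x = np.linspace(1, 5, 20)
        R = pcc_baseline(np.vstack([x, 3 * x, -2 * x + 20]))
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(1.0)
        assert np.all(np.diag(R) == 0)

    def test_pcc_matches_textbook_formula(self, rng):
        X = rng.random((3, 30))
        R = pcc_baseline(X)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = np.sum(xi * xj) / np.sqrt(np.sum(xi**2) * np.sum(xj**2))
                assert R[i, j] == pytest.approx(abs(r))

    def test_perfect_scores_give_auc_one(self):
        spec = make_recovery_spec(seed=0)
        _, _, auc = evaluate_edge_recovery(np.abs(spec.A), spec)
        assert auc == 1.0

    def test_random_scores_near_half(self, rng):
        spec = make_recovery_spec(seed=1)
        aucs = [evaluate_edge_recovery(rng.random(spec.A.shape), spec)[2]
                for _ in range(100)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_hand_three_node_roc(self):
        A = np.array([[0, 0.5, 0], [0, 0, 0], [0.3, 0, 0]])
        spec = SimulationSpec(A=A, b=np.zeros(3), x0=np.ones(3))
        scores = np.array([[0, 0.9, 0.1], [0.2, 0, 0.05], [0.8, 0.0, 0]])
        fpr, tpr, auc = evaluate_edge_recovery(scores, spec)
        # truth: 2 positives of 6 cells; both positives outrank all negatives
        assert auc == 1.0

    def test_single_class_truth_error(self):
        spec = SimulationSpec(A=np.zeros((2, 2)) + np.diag([-1.0, -1.0]),
                              b=np.zeros(2), x0=np.ones(2))
        with pytest.raises(ValueError):
            evaluate_edge_recovery(np.ones((2, 2)), spec)


class TestRecoverySpec:
    def test_model_class_matches_truth(self):
        spec = make_recovery_spec(seed=0)
        assert np.all(np.diag(spec.A) == 0)
        # every gene regulated (no affine source genes)
        assert np.all((spec.A != 0).sum(axis=1) >= 1)

    def test_single_seed_recovery_is_strong(self):
        from drynet.grn import PriorNetwork, infer_grn

        spec = make_recovery_spec(seed=0)
        tcm = simulate_timecourse(spec, max_step=0.01)
        traj = hermite_interpolate(tcm, n=tcm.times.size)
        grn = infer_grn(traj, prior=PriorNetwork.complete(spec.n_genes),
                        seed=0, prune=False)
        _, _, auc = evaluate_edge_recovery(grn.A, spec)
        assert auc >= 0.9
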