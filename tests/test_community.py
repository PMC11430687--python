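"""Multilayer modularity and the Louvain-style optimizer."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dynlayer import (compute_modularity, optimize, run_ensemble)
from dynlayer.community import supra_modularity_matrix
from dynlayer.multilayer import build_multilayer
from dynlayer.simulate import SimulationConfig, generate_group_timeseries
from dynlayer.tvfc import compute_tvfc

from conftest import make_network, random_network


def brute_modularity(net, labels, gamma=1.0):
    """Literal quadruple-sum evaluation of the multilayer quality function,
    independent of the package's supra-matrix code path."""
    A, omega = net.intra, net.omega
    T, N, _ = A.shape
    k = A.sum(axis=2)
    two_m = k.sum(axis=1)
    two_mu = two_m.sum() + 2 * omega.sum()
    total = 0.0
    for l in range(T):
        for r in range(T):
            for i in range(N):
                for j in range(N):
                    if labels[i, l] != labels[j, r]:
                        continue
                    if l == r:
                        null = (gamma * k[l, i] * k[l, j] / two_m[l]
                                if two_m[l] > 0 else 0.0)
                        total += A[l, i, j] - null
                    if i == j and abs(l - r) == 1:
                        total += omega[i, min(l, r)]
    return total / two_mu if two_mu else 0.0


class TestComputeModularity:
    def test_matches_independent_double_sum(self, rng):
        for _ in range(15):
            net = random_network(rng, n_nodes=4, n_layers=3)
            labels = rng.integers(1, 4, size=(4, 3))
            q = compute_modularity(net, labels)
            q_ref = brute_modularity(net, labels)
            assert q == pytest.approx(q_ref, rel=1e-12, abs=1e-13)

    def test_two_disjoint_triangles_single_layer_is_half(self):
        layer = np.zeros((6, 6))
        layer[:3, :3] = 1.0
        layer[3:, 3:] = 1.0
        np.fill_diagonal(layer, 0.0)
        net = make_network(layer[None], np.zeros((6, 0)))
        labels = np.repeat([1, 2], 3)[:, None]
        assert compute_modularity(net, labels) == pytest.approx(0.5)

    def test_zero_coupling_reduces_to_strength_weighted_layer_modularity(self, rng):
        net = random_network(rng, n_nodes=5, n_layers=3)
        net = dataclasses.replace(net, omega=np.zeros_like(net.omega))
        labels = rng.integers(1, 3, size=(5, 3))
        # independent per-layer Newman–Girvan modularities
        total, two_mu = 0.0, 0.0
        for l in range(net.n_layers):
            A = net.intra[l]
            k = A.sum(axis=1)
            two_m = k.sum()
            two_mu += two_m
            same = labels[:, l][:, None] == labels[:, l][None, :]
            if two_m > 0:
                q_l = ((A - np.outer(k, k) / two_m)[same]).sum() / two_m
                total += two_m * q_l
        assert compute_modularity(net, labels) == pytest.approx(
            total / two_mu, rel=1e-12)

    def test_all_singletons_zero_coupling_is_negative(self, rng):
        net = random_network(rng, n_nodes=4, n_layers=2)
        net = dataclasses.replace(net, omega=np.zeros_like(net.omega))
        labels = np.arange(1, 9).reshape(4, 2)
        assert compute_modularity(net, labels) < 0

    def test_invariant_under_label_permutation(self, rng):
        net = random_network(rng, n_nodes=5, n_layers=2)
        labels = rng.integers(1, 4, size=(5, 2))
        perm = {1: 7, 2: 3, 3: 11}
        permuted = np.vectorize(perm.get)(labels)
        assert compute_modularity(net, labels) == pytest.approx(
            compute_modularity(net, permuted), rel=1e-14)

    def test_empty_layer_contributes_no_null_term(self):
        intra = np.zeros((2, 3, 3))
        intra[1] = 1 - np.eye(3)
        net = make_network(intra, np.zeros((3, 1)))
        labels = np.ones((3, 2), dtype=int)
        assert np.isfinite(compute_modularity(net, labels))


class TestOptimize:
    def test_recovers_cliques_across_layers(self, two_cliques_3layers):
        part = optimize(two_cliques_3layers, seed=0)
        truth = np.repeat(np.repeat([1, 2], 3)[:, None], 3, axis=1)
        assert part.n_communities == 2
        assert adjusted_rand_score(truth.ravel(), part.labels.ravel()) == 1.0

    def test_recovers_exact_planted_blocks_in_weighted_stack(self):
        planted = np.repeat([1, 2], 6)
        layer = np.where(planted[:, None] == planted[None, :], 0.9, 0.1)
        np.fill_diagonal(layer, 0.0)
        net = make_network(np.stack([layer] * 3), np.ones((12, 2)))
        ens = run_ensemble(net, n_runs=5, base_seed=0)
        truth = np.repeat(planted[:, None], 3, axis=1)
        for run in ens.runs:
            assert adjusted_rand_score(truth.ravel(),
                                       run.labels.ravel()) == 1.0

    def test_generator_fixture_recovery_is_high_but_imperfect(self):
        # clamping keeps between-block coherence positive, so agreement with
        # the planted partition saturates below 1 on generated signals
        cfg = SimulationConfig(n_subjects_per_group=1, n_regions=16,
                               n_timepoints=30, n_modules=2,
                               epoch_length_mean=30, switch_prob=0.0,
                               within_block_corr=0.95, cross_block_corr=0.05,
                               noise_sd=0.05, seed=3)
        ts, truth = generate_group_timeseries(cfg, "A")
        net = build_multilayer(compute_tvfc(ts.series[0]),
                               similarity="cosine")
        ens = run_ensemble(net, n_runs=3, base_seed=1)
        for run in ens.runs:
            ari = adjusted_rand_score(truth.partition_schedules[0].ravel(),
                                      run.labels.ravel())
            assert ari > 0.6

    def test_single_node_single_layer_no_crash(self):
        net = make_network(np.zeros((1, 1, 1)), np.zeros((1, 0)))
        part = optimize(net, seed=0)
        assert part.n_communities == 1

    def test_returned_partition_is_locally_optimal(self, rng):
        net = random_network(rng, n_nodes=6, n_layers=3)
        part = optimize(net, seed=4)
        q0 = part.q_value
        flat = part.labels.copy()
        candidates = list(np.unique(flat)) + [flat.max() + 1]
        for i in range(6):
            for l in range(3):
                original = flat[i, l]
                for c in candidates:
                    if c == original:
                        continue
                    flat[i, l] = c
                    assert compute_modularity(net, flat) <= q0 + 1e-10
                flat[i, l] = original

    def test_q_value_consistent_with_compute_modularity(self, rng):
        net = random_network(rng, n_nodes=5, n_layers=3)
        part = optimize(net, seed=9)
        assert part.q_value == pytest.approx(
            compute_modularity(net, part.labels), rel=1e-12)

    def test_labels_are_contiguous_from_one(self, rng):
        net = random_network(rng, n_nodes=6, n_layers=2)
        part = optimize(net, seed=2)
        uniq = np.unique(part.labels)
        np.testing.assert_array_equal(uniq, np.arange(1, uniq.size + 1))


class TestEnsemble:
    def test_run_count_and_per_run_seeds(self, two_cliques_3layers):
        ens = run_ensemble(two_cliques_3layers, n_runs=7, base_seed=40)
        assert len(ens) == 7
        assert [run.seed for run in ens.runs] == list(range(40, 47))

    def test_reproducible_from_base_seed(self, rng):
        net = random_network(rng, n_nodes=6, n_layers=3)
        e1 = run_ensemble(net, n_runs=4, base_seed=11)
        e2 = run_ensemble(net, n_runs=4, base_seed=11)
        np.testing.assert_array_equal(e1.label_array(), e2.label_array())
        np.testing.assert_array_equal(e1.q_values, e2.q_values)

    def test_invalid_run_count_rejected(self, two_cliques_3layers):
        with pytest.raises(ValueError, match="n_runs"):
            run_ensemble(two_cliques_3layers, n_runs=0)

    def test_stronger_coupling_increases_temporal_persistence(self):
        cfg = SimulationConfig(n_subjects_per_group=1, n_regions=15,
                               n_timepoints=30, n_modules=3,
                               epoch_length_mean=10, switch_prob=0.3,
                               within_block_corr=0.7, cross_block_corr=0.1,
                               noise_sd=0.3, seed=8)
        ts, _ = generate_group_timeseries(cfg, "A")
        net = build_multilayer(compute_tvfc(ts.series[0]),
                               similarity="cosine")
        changes = []
        for mult in (0.5, 2.0, 8.0):
            scaled = dataclasses.replace(net, omega=np.clip(net.omega * mult,
                                                            0, None))
            ens = run_ensemble(scaled, n_runs=4, base_seed=3)
            changes.append(np.mean(
                [(r.labels[:, 1:] != r.labels[:, :-1]).sum(axis=1).mean()
                 for r in ens.runs]))
        assert changes[0] >= changes[1] - 0.1
        assert changes[1] >= changes[2] - 0.1


class TestSupraMatrix:
    def test_normalization_counts_degrees_and_couplings(self, rng):
        net = random_network(rng, n_nodes=4, n_layers=3)
        _, two_mu = supra_modularity_matrix(net)
        expected = net.intra.sum() + 2 * net.omega.sum()
        assert two_mu == pytest.approx(expected)

    def test_couplings_sit_on_adjacent_layer_diagonal(self, rng):
        net = random_network(rng, n_nodes=3, n_layers=2)
        B, _ = supra_modularity_matrix(net)
        dense = B.toarray()
        for i in range(3):
            assert dense[i, 3 + i] == pytest.approx(net.omega[i, 0])
            assert dense[3 + i, i] == pytest.approx(net.omega[i, 0])
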