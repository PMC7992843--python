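"""Synthetic generators: degree-sequence contracts, block structure, the
assortativity-targeting value sampler, and both corruption models."""

import numpy as np
import pytest

from netfilters.netcore import NodeValues, assortativity, largest_component
from netfilters.synthgen import (
    ChungLuConfig,
    DCSBMConfig,
    MCMCConfig,
    MCMCConvergenceError,
    ValueDistribution,
    _sample_degree_sequence,
    assign_values_mcmc,
    chung_lu_graph,
    dcsbm_graph,
    expected_mean_degree,
    modular_values,
    permute_noise,
    rewire_edges,
)

from conftest import random_graph, random_values


class TestChungLu:
    def test_weight_sequence_capped_at_k_max(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ks = _sample_degree_sequence(rng, 100, 3.0, 1, 17)
            assert ks.max() <= 17.0
            assert ks.min() >= 1.0

    def test_sequence_mean_matches_truncated_expectation(self):
        """Empirical mean of sampled expected degrees vs the analytic mean of
        the truncated power law, within 3 standard errors."""
        rng = np.random.default_rng(1)
        draws = np.concatenate(
            [_sample_degree_sequence(rng, 100, 3.0, 1, 17) for _ in range(1000)]
        )
        expect = expected_mean_degree(3.0, 1, 17)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expect) < 3 * se

    def test_degenerate_two_nodes(self):
        net = chung_lu_graph(ChungLuConfig(n=2, seed=4))
        assert net.n_nodes <= 2 and net.n_edges <= 1

    def test_returns_connected_graph(self):
        for seed in range(5):
            net = chung_lu_graph(ChungLuConfig(seed=seed))
            assert largest_component(net) == net

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ChungLuConfig(n=1)
        with pytest.raises(ValueError):
            ChungLuConfig(gamma_degree=1.0)


class TestDCSBM:
    def test_total_nodes_before_extraction(self):
        # largest component of a lambda=1 draw cannot exceed one module;
        # the full graph has kappa * n_r = 500 nodes by construction
        net, part = dcsbm_graph(DCSBMConfig(seed=0))
        assert net.n_nodes <= 500
        assert part.kappa <= 5
        assert set(part.labels) == set(net.node_ids)

    def test_planted_limit_no_between_edges(self):
        net, part = dcsbm_graph(DCSBMConfig(lam=1.0, seed=1))
        for u, v in net.edges():
            assert part[u] == part[v]

    def test_random_limit_within_module_fraction(self):
        """At lam=0 the within-module edge fraction matches the
        configuration-model expectation sum_r (K_r / 2m)^2."""
        within = total = expect_num = expect_den = 0.0
        for seed in range(60):
            net, part = dcsbm_graph(DCSBMConfig(lam=0.0, seed=seed))
            k = net.degrees()
            labels = np.array([str(part[v]) for v in net.node_ids])
            two_m = k.sum()
            expect_num += sum(
                (k[labels == lab].sum() / two_m) ** 2 for lab in np.unique(labels)
            )
            expect_den += 1
            for u, v in net.edges():
                within += part[u] == part[v]
                total += 1
        frac = within / total
        expect = expect_num / expect_den
        # binomial standard error at the observed edge count
        se = np.sqrt(expect * (1 - expect) / total)
        assert abs(frac - expect) < 3 * se


class TestValueMCMC:
    def test_null_target_converges(self):
        net = chung_lu_graph(ChungLuConfig(seed=2))
        x = assign_values_mcmc(net, ValueDistribution(), MCMCConfig(r_target=0.0, seed=2))
        assert abs(assortativity(net, x)) <= 0.009

    @pytest.mark.parametrize("r_target", [0.8, -0.8])
    def test_extreme_targets_within_tolerance(self, r_target):
        for seed in range(3):
            net = chung_lu_graph(ChungLuConfig(seed=seed + 10))
            x = assign_values_mcmc(
                net, ValueDistribution(), MCMCConfig(r_target=r_target, seed=seed)
            )
            assert abs(assortativity(net, x) - r_target) <= 0.009

    def test_marginals_follow_distribution(self):
        net = chung_lu_graph(ChungLuConfig(n=300, seed=3))
        x = assign_values_mcmc(
            net, ValueDistribution(mu=100.0, sigma2=100.0), MCMCConfig(r_target=0.3, seed=3)
        )
        arr = x.to_array(net)
        assert abs(arr.mean() - 100.0) < 4 * 10.0 / np.sqrt(arr.size)

    def test_proposal_budget_error(self):
        net = chung_lu_graph(ChungLuConfig(seed=4))
        with pytest.raises(MCMCConvergenceError):
            assign_values_mcmc(
                net,
                ValueDistribution(),
                MCMCConfig(r_target=0.9, beta_tol=1e-6, max_proposals=10, seed=0),
            )

    def test_worsening_proposals_rejected(self):
        """Hill-climbing acceptance: the running distance to the target never
        increases over the chain, measured by re-running with checkpoints."""
        net = chung_lu_graph(ChungLuConfig(seed=5))
        dist = ValueDistribution()
        deltas = []
        for cap in (20, 100, 400, 2000):
            try:
                x = assign_values_mcmc(
                    net, dist, MCMCConfig(r_target=0.8, max_proposals=cap, seed=7)
                )
                deltas.append(abs(assortativity(net, x) - 0.8))
                break
            except MCMCConvergenceError:
                continue
        # if any prefix converged, its final distance is within tolerance
        assert not deltas or deltas[0] <= 0.009


@pytest.fixture(scope="module")
def graph_and_partition():
    return dcsbm_graph(DCSBMConfig(seed=11))


class TestModularValues:
    def test_all_assortative_within_band(self, graph_and_partition):
        net, part = graph_and_partition
        x = modular_values(net, part, [110, 80, 60, 40, 20][: part.kappa], 25.0,
                           n_assortative=part.kappa, seed=1)
        for _, members in part.modules().items():
            sub = largest_component(net.subgraph(members))
            if sub.n_edges == 0:
                continue
            r = assortativity(sub, x.restrict(sub.node_ids))
            assert 0.391 <= r <= 0.709

    def test_no_assortative_all_negative(self, graph_and_partition):
        net, part = graph_and_partition
        x = modular_values(net, part, [110, 80, 60, 40, 20][: part.kappa], 25.0,
                           n_assortative=0, seed=2)
        for _, members in part.modules().items():
            sub = largest_component(net.subgraph(members))
            if sub.n_edges == 0:
                continue
            assert assortativity(sub, x.restrict(sub.node_ids)) < 0

    def test_module_means_match_configuration(self, graph_and_partition):
        net, part = graph_and_partition
        means = [110.0, 80.0, 60.0, 40.0, 20.0][: part.kappa]
        x = modular_values(net, part, means, 25.0, n_assortative=2, seed=3)
        labels = sorted(part.modules(), key=str)
        for mu, lab in zip(means, labels):
            vals = [x[v] for v in part.modules()[lab]]
            assert abs(np.mean(vals) - mu) < 4 * 5.0 / np.sqrt(len(vals))

    def test_mean_count_validation(self, graph_and_partition):
        net, part = graph_and_partition
        with pytest.raises(ValueError):
            modular_values(net, part, [1.0], 25.0, 0, seed=0)


class TestPermuteNoise:
    def test_zero_fraction_identity(self, triangle):
        x = random_values(triangle, seed=0)
        out, selected = permute_noise(x, 0.0, seed=1)
        assert out == x and selected == []

    def test_full_fraction_conserves_multiset(self):
        x = NodeValues({"a": 1.0, "b": 2.0, "c": 3.0})
        out, selected = permute_noise(x, 1.0, seed=2)
        assert sorted(out.values.values()) == [1.0, 2.0, 3.0]
        assert len(selected) == 3

    def test_exact_count_quarter(self):
        net = random_graph(100, 0.05, seed=3)
        x = random_values(net, seed=3)
        _, selected = permute_noise(x, 0.25, seed=4)
        assert len(selected) == 25

    def test_within_partition_conserves_per_module(self):
        from netfilters.netcore import Partition

        net = random_graph(40, 0.1, seed=5)
        x = random_values(net, seed=5)
        part = Partition({v: i % 4 for i, v in enumerate(net.node_ids)})
        out, _ = permute_noise(x, 1.0, within=part, seed=6)
        for _, members in part.modules().items():
            assert sorted(out[v] for v in members) == pytest.approx(
                sorted(x[v] for v in members)
            )


class TestRewireEdges:
    def test_zero_fraction_identity(self, two_cliques_bridge):
        assert rewire_edges(two_cliques_bridge, 0.0, seed=0) == two_cliques_bridge

    @pytest.mark.parametrize("fraction", [0.3, 0.9])
    def test_edge_count_and_node_set_preserved(self, fraction):
        net = random_graph(50, 0.08, seed=7)
        out = rewire_edges(net, fraction, seed=8)
        assert out.n_edges == net.n_edges
        assert out.node_ids == net.node_ids

    def test_ninety_percent_retains_few_originals(self):
        # floor(0.9 m) originals removed; deleted edges can only reappear by
        # uniform coincidence, which is rare on a sparse graph
        net = random_graph(200, 0.01, seed=9)
        m = net.n_edges
        out = rewire_edges(net, 0.9, seed=10)
        assert out.n_edges == m
        kept = set(net.edges()) & set(out.edges())
        assert len(kept) <= m - int(np.floor(0.9 * m)) + 8

    def test_simple_graph_invariants(self):
        net = random_graph(30, 0.15, seed=11)
        out = rewire_edges(net, 0.5, seed=12)
        assert all(u != v for u, v in out.edges())
        assert len(out.edges()) == len(set(out.edges()))


def test_null_assortativity_calibration():
    """I.i.d. values on heavy-tailed graphs are unassorted on average."""
    rs = []
    rng = np.random.default_rng(99)
    for seed in range(500):
        net = chung_lu_graph(ChungLuConfig(seed=seed))
        if net.n_edges < 2:
            continue
        x = NodeValues.from_array(net, rng.normal(100, 10, net.n_nodes))
        try:
            rs.append(assortativity(net, x))
        except Exception:
            continue
    assert abs(np.mean(rs)) < 0.05
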