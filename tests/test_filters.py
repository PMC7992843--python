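"""Network filters: closed-form arithmetic, matrix-form oracles, fixed
points, boundedness, synchronicity and the patchwork branch contracts."""

import numpy as np
import pytest

from netfilters.filters import (
    SharpParams,
    mean_filter,
    median_filter,
    patchwork_filter,
    sharp_filter,
)
from netfilters.netcore import Network, NodeValues, Partition, assortativity

from conftest import random_graph, random_values


class TestMeanFilter:
    def test_path_arithmetic(self, path_graph):
        x = NodeValues({"a": 0.0, "b": 3.0, "c": 6.0})
        out = mean_filter(path_graph, x)
        assert out["b"] == pytest.approx(3.0)
        assert out["a"] == pytest.approx(1.5)
        assert out["c"] == pytest.approx(4.5)

    def test_constant_fixed_point(self, triangle):
        x = NodeValues({"a": 5.0, "b": 5.0, "c": 5.0})
        assert mean_filter(triangle, x) == x

    def test_isolated_node_passthrough(self):
        net = Network.from_edges([("a", "b")], nodes=["a", "b", "z"])
        out = mean_filter(net, NodeValues({"a": 1.0, "b": 3.0, "z": 9.0}))
        assert out["z"] == 9.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matrix_form_oracle(self, seed):
        """(D + I)^-1 (A + I) x reproduces the neighborhood-mean form."""
        net = random_graph(20, 0.2, seed=seed)
        x = random_values(net, seed=seed + 5)
        a = net.adjacency().toarray()
        d = np.diag(net.degrees())
        oracle = np.linalg.solve(d + np.eye(20), (a + np.eye(20)) @ x.to_array(net))
        assert mean_filter(net, x).to_array(net) == pytest.approx(oracle, abs=1e-12)

    def test_honors_edge_weights(self):
        net = Network.from_edges([("a", "b", 3.0), ("a", "c", 1.0)])
        out = mean_filter(net, NodeValues({"a": 0.0, "b": 2.0, "c": 4.0}))
        assert out["a"] == pytest.approx((0.0 + 3.0 * 2.0 + 1.0 * 4.0) / 3)


class TestMedianFilter:
    def test_star_midpoint_convention(self, star_graph):
        x = NodeValues({"h": 10.0, "l1": 1.0, "l2": 2.0, "l3": 3.0})
        out = median_filter(star_graph, x)
        assert out["h"] == pytest.approx(2.5)  # median{1,2,3,10}
        assert out["l1"] == pytest.approx(5.5)  # median{1,10}

    def test_constant_fixed_point(self, triangle):
        x = NodeValues({"a": 2.0, "b": 2.0, "c": 2.0})
        assert median_filter(triangle, x) == x


class TestSharpFilter:
    def test_triangle_arithmetic(self, triangle):
        x = NodeValues({"a": 1.0, "b": 2.0, "c": 3.0})
        out = sharp_filter(triangle, x, SharpParams(alpha_sharp=0.8))
        assert out["a"] == pytest.approx(0.8 * (1.0 - 2.0) + 2.0)

    def test_constant_fixed_point(self, triangle):
        x = NodeValues({"a": 4.0, "b": 4.0, "c": 4.0})
        assert sharp_filter(triangle, x) == x

    def test_alpha_zero_limit_collapses_to_mean(self, path_graph):
        x = NodeValues({"a": 1.0, "b": 5.0, "c": 9.0})
        out = sharp_filter(path_graph, x, SharpParams(alpha_sharp=1e-12))
        assert out.to_array(path_graph) == pytest.approx(np.full(3, 5.0), abs=1e-9)

    def test_baseline_mean_override(self, path_graph):
        x = NodeValues({"a": 1.0, "b": 5.0, "c": 9.0})
        out = sharp_filter(path_graph, x, baseline_mean=0.0)
        default = sharp_filter(path_graph, x)
        for v in path_graph.node_ids:
            assert out[v] == pytest.approx(default[v] - 5.0)


class TestLocalProperties:
    @pytest.mark.parametrize("filt", [mean_filter, median_filter])
    @pytest.mark.parametrize("seed", range(3))
    def test_smoothers_bounded_by_closed_neighborhood(self, filt, seed):
        net = random_graph(25, 0.15, seed=seed)
        x = random_values(net, seed=seed + 50)
        out = filt(net, x)
        nbrs = net.neighbor_indices()
        xv = x.to_array(net)
        ov = out.to_array(net)
        for i in range(net.n_nodes):
            hood = np.append(xv[nbrs[i]], xv[i])
            assert hood.min() - 1e-12 <= ov[i] <= hood.max() + 1e-12

    @pytest.mark.parametrize("filt", [mean_filter, median_filter, sharp_filter])
    def test_permutation_equivariance(self, filt):
        """Relabeling nodes and permuting values permutes the output."""
        net = random_graph(15, 0.25, seed=4)
        x = random_values(net, seed=9)
        mapping = {v: f"z{ord(v[-1]) * 7 % 97:02d}{i}" for i, v in enumerate(net.node_ids)}
        relabeled = Network.from_edges(
            [(mapping[u], mapping[v]) for u, v in net.edges()],
            nodes=[mapping[v] for v in net.node_ids],
        )
        xr = NodeValues({mapping[v]: x[v] for v in net.node_ids})
        out = filt(net, x)
        out_r = filt(relabeled, xr)
        for v in net.node_ids:
            assert out_r[mapping[v]] == pytest.approx(out[v], abs=1e-12)


class TestPatchworkFilter:
    def test_single_assortative_module_reduces_to_mean(self):
        # a path with monotone values is strongly assortative
        nodes = [f"n{i:02d}" for i in range(10)]
        net = Network.from_edges(list(zip(nodes, nodes[1:])))
        x = NodeValues({v: float(i) for i, v in enumerate(nodes)})
        part = Partition({v: "all" for v in nodes})
        assert assortativity(net, x) > 0
        assert patchwork_filter(net, x, part) == mean_filter(net, x)

    def test_bridge_edge_has_no_effect(self, two_cliques_bridge):
        net = two_cliques_bridge
        part = Partition({v: v[0] for v in net.node_ids})
        x = random_values(net, seed=3)
        with_bridge = patchwork_filter(net, x, part)
        edges = [e for e in net.edges() if e != ("a3", "b0")]
        no_bridge = Network.from_edges(edges, nodes=net.node_ids)
        without = patchwork_filter(no_bridge, x, part)
        for v in net.node_ids:
            assert with_bridge[v] == pytest.approx(without[v], abs=1e-12)

    def test_disassortative_module_uses_sharp_with_module_mean(self):
        net = Network.from_edges([("a", "b")])
        x = NodeValues({"a": 0.0, "b": 10.0})  # single edge: r = -1
        part = Partition({"a": "m", "b": "m"})
        out = patchwork_filter(net, x, part)
        expected = sharp_filter(net, x, baseline_mean=5.0)
        assert out == expected

    def test_module_without_internal_edges_passes_through(self):
        net = Network.from_edges([("a", "b"), ("b", "c")])
        part = Partition({"a": "m1", "c": "m1", "b": "m2"})
        x = NodeValues({"a": 1.0, "b": 2.0, "c": 3.0})
        out = patchwork_filter(net, x, part)
        assert out["a"] == 1.0 and out["c"] == 3.0 and out["b"] == 2.0

    def test_constant_module_falls_to_smooth_branch(self, triangle):
        part = Partition({"a": "m", "b": "m", "c": "m"})
        x = NodeValues({"a": 1.0, "b": 1.0, "c": 1.0})
        assert patchwork_filter(triangle, x, part) == x

    def test_node_isolated_within_module_keeps_value(self, two_cliques_bridge):
        net = two_cliques_bridge
        labels = {v: "A" for v in net.node_ids}
        labels["b0"] = "solo"  # b0's only same-module neighbors removed
        x = random_values(net, seed=6)
        out = patchwork_filter(net, x, Partition(labels))
        assert out["b0"] == x["b0"]
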