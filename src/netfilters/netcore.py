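"""Core data model: networks, node measurements, partitions, and assortativity.

A :class:`Network` is an undirected, unweighted (optionally weighted) simple
graph with opaque string node identifiers. All matrix and vector views use one
canonical node ordering — the lexicographically sorted node IDs — so that
repeated runs produce bit-identical linear-algebra objects.

:class:`NodeValues` carries one real measurement per node and
:class:`Partition` a module label per node. The numeric assortativity
coefficient measures whether a scalar node attribute is correlated (r > 0) or
anti-correlated (r < 0) across edges.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NodeValues",
    "Partition",
    "UndefinedAssortativityError",
    "assortativity",
    "largest_component",
    "read_network",
    "write_network",
    "read_values",
    "write_values",
    "read_partition",
    "write_partition",
]


class UndefinedAssortativityError(ValueError):
    """Raised when the assortativity coefficient has a zero denominator
    (constant node values)."""


class Network:
    """Undirected simple graph with a canonical (sorted) node ordering.

    Parameters
    ----------
    graph:
        A :class:`networkx.Graph`. Self-loops are dropped (with a warning) and
        parallel edges cannot occur by Graph semantics. Edge weights, when
        present under the ``"weight"`` key, must be positive.
    """

    def __init__(self, graph: nx.Graph):
        g = nx.Graph(graph)
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.warning("dropping %d self-loop(s)", len(loops))
            g.remove_edges_from(loops)
        self._g = g
        self.node_ids: tuple[str, ...] = tuple(sorted(g.nodes, key=str))
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] = (),
        weights: Mapping[tuple, float] | None = None,
    ) -> "Network":
        g = nx.Graph()
        g.add_nodes_from(str(v) for v in nodes)
        for e in edges:
            u, v = str(e[0]), str(e[1])
            w = 1.0
            if weights is not None:
                w = float(weights.get((e[0], e[1]), weights.get((e[1], e[0]), 1.0)))
            elif len(e) > 2:
                w = float(e[2])
            if w <= 0:
                raise ValueError(f"edge weight must be positive, got {w} on ({u}, {v})")
            g.add_edge(u, v, weight=w)
        return cls(g)

    # -- basic views ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (treat as read-only)."""
        return self._g

    def index_of(self, node: str) -> int:
        return self._index[node]

    def has_node(self, node: str) -> bool:
        return node in self._index

    def edges(self) -> list[tuple[str, str]]:
        """Edges as (u, v) with u < v, sorted — a canonical edge list."""
        return sorted((min(u, v), max(u, v)) for u, v in self._g.edges)

    def degrees(self) -> np.ndarray:
        """Degree k_i in canonical node order (unweighted edge counts)."""
        return np.array([self._g.degree(v) for v in self.node_ids], dtype=float)

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        """Sparse adjacency A in canonical node order.

        With ``weighted=True``, entries are edge weights (default 1).
        """
        weight = "weight" if weighted else None
        return nx.to_scipy_sparse_array(
            self._g, nodelist=list(self.node_ids), weight=weight, format="csr"
        ).astype(float)

    def neighbor_indices(self) -> list[np.ndarray]:
        """Per node (canonical order), the integer indices of its neighbors."""
        return [
            np.fromiter(
                (self._index[u] for u in self._g.neighbors(v)), dtype=np.int64
            )
            for v in self.node_ids
        ]

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        """Induced subgraph on ``nodes`` (retains weights)."""
        return Network(self._g.subgraph(list(nodes)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.node_ids == other.node_ids and self.edges() == other.edges()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n={self.n_nodes}, m={self.n_edges})"


class NodeValues:
    """A real measurement x_i per node, keyed by node ID."""

    def __init__(self, values: Mapping[str, float]):
        vals = {str(k): float(v) for k, v in values.items()}
        bad = [k for k, v in vals.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite values for nodes {bad[:5]}")
        self.values: dict[str, float] = vals

    def __getitem__(self, node: str) -> float:
        return self.values[node]

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, NodeValues):
            return NotImplemented
        return self.values == other.values

    def to_array(self, net: Network) -> np.ndarray:
        """Values aligned to ``net``'s canonical node order.

        Raises ``KeyError`` if any network node lacks a value.
        """
        missing = [v for v in net.node_ids if v not in self.values]
        if missing:
            raise KeyError(f"missing values for nodes {missing[:5]}")
        return np.array([self.values[v] for v in net.node_ids], dtype=float)

    @classmethod
    def from_array(cls, net: Network, x: np.ndarray) -> "NodeValues":
        x = np.asarray(x, dtype=float)
        if x.shape != (net.n_nodes,):
            raise ValueError(f"expected shape ({net.n_nodes},), got {x.shape}")
        return cls(dict(zip(net.node_ids, x)))

    def restrict(self, nodes: Iterable[str]) -> "NodeValues":
        return NodeValues({v: self.values[v] for v in nodes})


class Partition:
    """A module label s_i per node."""

    def __init__(self, labels: Mapping[str, object]):
        if not labels:
            raise ValueError("partition must label at least one node")
        self.labels: dict[str, object] = {str(k): v for k, v in labels.items()}

    @property
    def kappa(self) -> int:
        """Number of nonempty modules."""
        return len(set(self.labels.values()))

    def __getitem__(self, node: str) -> object:
        return self.labels[node]

    def modules(self) -> dict[object, list[str]]:
        """Label -> sorted list of member node IDs."""
        out: dict[object, list[str]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, []).append(node)
        return {lab: sorted(members) for lab, members in out.items()}

    def restrict(self, nodes: Iterable[str]) -> "Partition":
        return Partition({v: self.labels[v] for v in nodes})

    def to_array(self, net: Network) -> np.ndarray:
        """Integer labels in canonical node order (labels densified 0..kappa-1)."""
        uniq = {lab: i for i, lab in enumerate(sorted(set(self.labels.values()), key=str))}
        return np.array([uniq[self.labels[v]] for v in net.node_ids], dtype=np.int64)


# -- operations -----------------------------------------------------------


def largest_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken in favor of the component containing the
    lexicographically smallest node ID.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return net.subgraph(comps[0])


def assortativity(net: Network, x: NodeValues) -> float:
    """Numeric assortativity coefficient r of node values across edges.

    .. math::

        r = \\frac{\\sum_{ij} (A_{ij} - k_i k_j / 2m)\\, x_i x_j}
                  {\\sum_{ij} (k_i \\delta_{ij} - k_i k_j / 2m)\\, x_i x_j}

    which is the Pearson correlation of the value pairs at the two ends of
    every edge stub. r lies in [-1, 1] up to floating error.

    Raises
    ------
    UndefinedAssortativityError
        If the values are constant over nodes with degree > 0 (zero
        denominator).
    ValueError
        If the network has no edges.
    """
    if net.n_edges == 0:
        raise ValueError("assortativity requires at least one edge")
    xv = x.to_array(net)
    k = net.degrees()
    a = net.adjacency()
    two_m = k.sum()
    s_edges = float(xv @ (a @ xv))  # sum_ij A_ij x_i x_j
    t = float(k @ xv)
    num = s_edges - t * t / two_m
    den = float(k @ (xv * xv)) - t * t / two_m
    if den <= 0 or np.isclose(den, 0.0, atol=1e-12 * max(1.0, abs(num))):
        raise UndefinedAssortativityError(
            "assortativity undefined: constant values (zero denominator)"
        )
    return num / den


# -- file I/O -------------------------------------------------------------


def read_network(path: str | Path, format: str = "edgelist") -> Network:
    """Read a network from an edge-list TSV or a GraphML file.

    The edge list has two tab-separated ID columns and an optional third
    positive-weight column, no header. Duplicate edges are collapsed and
    self-loops dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        net = Network(nx.Graph(g))
    elif format == "edgelist":
        g = nx.Graph()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) == 1:  # tolerate space-separated files
                    parts = line.split()
                if len(parts) not in (2, 3):
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                    )
                u, v = parts[0], parts[1]
                if u == v:
                    logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                    g.add_node(u)
                    continue
                try:
                    w = float(parts[2]) if len(parts) == 3 else 1.0
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                g.add_edge(u, v, weight=w)
        net = Network(g)
    else:
        raise ValueError(f"unknown format {format!r}")
    if net.n_nodes == 0:
        raise ValueError(f"{path}: empty graph")
    return net


def write_network(net: Network, path: str | Path, format: str = "edgelist") -> None:
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            for u, v in net.edges():
                w = net.graph.edges[u, v].get("weight", 1.0)
                if w == 1.0:
                    fh.write(f"{u}\t{v}\n")
                else:
                    fh.write(f"{u}\t{v}\t{w:g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_values(path: str | Path) -> NodeValues:
    """Node values from a CSV with header ``node,value``."""
    df = pd.read_csv(path, dtype={"node": str})
    return NodeValues(dict(zip(df["node"], df["value"])))


def write_values(x: NodeValues, path: str | Path) -> None:
    pd.DataFrame(
        sorted(x.values.items()), columns=["node", "value"]
    ).to_csv(path, index=False)


def read_partition(path: str | Path) -> Partition:
    """Node partition from a CSV with header ``node,module``."""
    df = pd.read_csv(path, dtype={"node": str, "module": str})
    return Partition(dict(zip(df["node"], df["module"])))


def write_partition(p: Partition, path: str | Path) -> None:
    pd.DataFrame(
        sorted((n, str(m)) for n, m in p.labels.items()), columns=["node", "module"]
    ).to_csv(path, index=False)
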