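"""Synthetic benchmark generators: heavy-tailed random graphs, modular
degree-corrected block-model graphs, node values with a target assortativity,
and the two corruption models (value permutation, edge rewiring).

The generators emulate benchmark conditions in which a network filter's value
can be measured against known ground truth: Chung-Lu graphs with a truncated
power-law degree distribution carry Normal node values whose assortativity is
driven to a target by a hill-climbing Markov chain; planted-partition
degree-corrected SBM graphs carry module-specific value distributions with
per-module assortativity signs. Measurement noise permutes a fixed fraction of
values (conserving their multiset); network noise rewires a fixed fraction of
edges (conserving the edge count).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .netcore import (
    Network,
    NodeValues,
    Partition,
    largest_component,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChungLuConfig",
    "DCSBMConfig",
    "ValueDistribution",
    "MCMCConfig",
    "MCMCConvergenceError",
    "chung_lu_graph",
    "dcsbm_graph",
    "expected_mean_degree",
    "assign_values_mcmc",
    "modular_values",
    "permute_noise",
    "rewire_edges",
]

_MAX_SEQUENCE_REJECTIONS = 10_000
_MAX_REWIRE_REJECTIONS = 100_000


@dataclass
class ChungLuConfig:
    """Chung-Lu random-graph settings.

    Degrees are drawn i.i.d. from Pr(k) ∝ k^(-gamma_degree) on k >= k_min and
    the whole sequence is redrawn whenever any draw exceeds ``k_max`` (which
    suppresses star-like subgraphs). Edge (i, j) is placed independently with
    probability min(1, k_i k_j / Σk).
    """

    n: int = 100
    gamma_degree: float = 3.0
    k_min: int = 1
    k_max: int = 17
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.gamma_degree <= 1:
            raise ValueError("gamma_degree must be > 1")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")


@dataclass
class DCSBMConfig:
    """Planted-partition degree-corrected SBM settings.

    The community mixing matrix interpolates between a perfectly modular graph
    and a degree-matched random graph:
    ω_rs = lam * ω_planted_rs + (1 - lam) * ω_random_rs, with ω_planted
    diagonal (each module's degree mass stays internal) and
    ω_random_rs = K_r K_s / 2m for module degree sums K_r.
    """

    kappa: int = 5
    n_r: int = 100
    lam: float = 0.85
    gamma_degree: float = 3.0
    k_min: int = 1
    k_max: int = 17
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.n_r < 1:
            raise ValueError("n_r must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")


@dataclass
class ValueDistribution:
    """Normal value marginal N(mu, sigma2)."""

    mu: float = 100.0
    sigma2: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class MCMCConfig:
    """Settings for the assortativity-targeting value sampler."""

    r_target: float = 0.0
    beta_tol: float = 0.009
    max_proposals: int = 200_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 < self.r_target < 1.0:
            raise ValueError("r_target must lie in (-1, 1)")
        if self.beta_tol <= 0:
            raise ValueError("beta_tol must be positive")
        if self.max_proposals < 1:
            raise ValueError("max_proposals must be >= 1")


class MCMCConvergenceError(RuntimeError):
    """The value sampler exhausted its proposal budget; re-draw with a new
    seed (the target may be unreachable on this graph)."""


def _sample_degree_sequence(
    rng: np.random.Generator, n: int, gamma: float, k_min: int, k_max: int
) -> np.ndarray:
    """Draw n i.i.d. power-law expected degrees, rejecting whole sequences
    with any draw above k_max.

    Expected degrees are real-valued, drawn by inverse CDF from the Pareto
    density p(k) ∝ k^(-gamma) on [k_min, ∞) — the classical Chung-Lu weight
    formulation, under which each node's realized degree follows the weight
    in expectation.
    """
    for _ in range(_MAX_SEQUENCE_REJECTIONS):
        ks = k_min * (1.0 - rng.random(n)) ** (-1.0 / (gamma - 1.0))
        if ks.max() <= k_max:
            return ks
    raise RuntimeError(
        f"degree sequence rejected {_MAX_SEQUENCE_REJECTIONS} times "
        f"(k_max={k_max} too tight for gamma={gamma})"
    )


def expected_mean_degree(gamma: float, k_min: int, k_max: int) -> float:
    """Mean of the truncated Pareto expected-degree distribution on
    [k_min, k_max] with density ∝ k^(-gamma)."""
    a, b = float(k_min), float(k_max)
    if gamma == 2.0:  # pragma: no cover - degenerate integral
        return (np.log(b) - np.log(a)) / (a**-1 - b**-1)
    norm = (a ** (1 - gamma) - b ** (1 - gamma)) / (gamma - 1)
    mean = (a ** (2 - gamma) - b ** (2 - gamma)) / (gamma - 2)
    return mean / norm


def _node_labels(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"v{i:0{width}d}" for i in range(n)]


def chung_lu_graph(cfg: ChungLuConfig) -> Network:
    """Generate a Chung-Lu random graph and return its largest component."""
    rng = np.random.default_rng(cfg.seed)
    ks = _sample_degree_sequence(rng, cfg.n, cfg.gamma_degree, cfg.k_min, cfg.k_max)
    total = ks.sum()
    p = np.minimum(1.0, np.outer(ks, ks) / total)
    iu, ju = np.triu_indices(cfg.n, k=1)
    hit = rng.random(iu.size) < p[iu, ju]
    labels = _node_labels(cfg.n)
    edges = [(labels[i], labels[j]) for i, j in zip(iu[hit], ju[hit])]
    net = Network.from_edges(edges, nodes=labels)
    return largest_component(net)


def dcsbm_graph(cfg: DCSBMConfig) -> tuple[Network, Partition]:
    """Generate a planted-partition DC-SBM graph.

    Returns the largest component and the true planted partition restricted
    to it.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.kappa * cfg.n_r
    ks = _sample_degree_sequence(rng, n, cfg.gamma_degree, cfg.k_min, cfg.k_max)
    groups = np.repeat(np.arange(cfg.kappa), cfg.n_r)
    big_k = np.array([ks[groups == r].sum() for r in range(cfg.kappa)])
    two_m = ks.sum()
    omega = cfg.lam * np.diag(big_k) + (1 - cfg.lam) * np.outer(big_k, big_k) / two_m
    theta = ks / big_k[groups]
    p = np.minimum(1.0, np.outer(theta, theta) * omega[np.ix_(groups, groups)])
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(iu.size) < p[iu, ju]
    labels = _node_labels(n)
    edges = [(labels[i], labels[j]) for i, j in zip(iu[hit], ju[hit])]
    net = largest_component(Network.from_edges(edges, nodes=labels))
    part = Partition({labels[i]: f"m{groups[i]}" for i in range(n)}).restrict(
        net.node_ids
    )
    return net, part


def assign_values_mcmc(
    net: Network, dist: ValueDistribution, cfg: MCMCConfig
) -> NodeValues:
    """Draw node values from ``dist`` with assortativity within ``beta_tol``
    of ``r_target`` by single-node redraw hill climbing.

    Each node starts with an i.i.d. draw. A proposal redraws one uniformly
    chosen node's value i.i.d. and is accepted iff it does not worsen
    Δ = |r - r_target|; the chain stops once Δ <= beta_tol. The value
    marginals therefore remain draws from ``dist``.

    Raises
    ------
    MCMCConvergenceError
        After ``max_proposals`` proposals without reaching the tolerance.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if net.n_edges == 0:
        raise ValueError("need at least 1 edge")
    rng = np.random.default_rng(cfg.seed)
    sd = math.sqrt(dist.sigma2)
    n = net.n_nodes
    k = net.degrees()
    nbrs = net.neighbor_indices()
    two_m = k.sum()

    x = rng.normal(dist.mu, sd, size=n)
    adj = net.adjacency()
    # running statistics for O(deg) incremental assortativity updates
    s_edge = float(x @ (adj @ x))  # Σ_ij A_ij x_i x_j
    t = float(k @ x)
    q = float(k @ (x * x))

    def r_of(s_e: float, t_: float, q_: float) -> float:
        c = t_ * t_ / two_m
        den = q_ - c
        if den <= 0:
            return math.nan
        return (s_e - c) / den

    delta = abs(r_of(s_edge, t, q) - cfg.r_target)
    proposals = 0
    while delta > cfg.beta_tol or math.isnan(delta):
        if proposals >= cfg.max_proposals:
            raise MCMCConvergenceError(
                f"no convergence to r={cfg.r_target} within "
                f"{cfg.max_proposals} proposals; re-draw with a new seed"
            )
        proposals += 1
        i = int(rng.integers(n))
        xi_new = rng.normal(dist.mu, sd)
        d = xi_new - x[i]
        nb_sum = float(x[nbrs[i]].sum())
        s_edge2 = s_edge + 2.0 * d * nb_sum
        t2 = t + k[i] * d
        q2 = q + k[i] * (xi_new * xi_new - x[i] * x[i])
        delta2 = abs(r_of(s_edge2, t2, q2) - cfg.r_target)
        if math.isnan(delta2):
            continue  # degenerate proposal: restore
        if delta2 <= delta or math.isnan(delta):
            x[i] = xi_new
            s_edge, t, q = s_edge2, t2, q2
            delta = delta2
            if delta <= cfg.beta_tol:
                # guard against float drift in the running sums
                s_edge = float(x @ (adj @ x))
                t = float(k @ x)
                q = float(k @ (x * x))
                delta = abs(r_of(s_edge, t, q) - cfg.r_target)
    return NodeValues.from_array(net, x)


def modular_values(
    net: Network,
    part: Partition,
    means: list[float],
    sigma2: float,
    n_assortative: int,
    r_band: tuple[float, float] = (0.4, 0.7),
    seed: int | None = None,
    beta_tol: float = 0.009,
    max_proposals: int = 200_000,
) -> NodeValues:
    """Module-specific Normal values with per-module assortativity signs.

    Module j's values come from N(means_j, sigma2). Exactly ``n_assortative``
    modules (chosen uniformly at random) get a target assortativity drawn
    uniformly from ``r_band``; the rest get a target drawn uniformly from the
    negated band. Each module converges via the single-node-redraw chain run
    on the largest component of its induced subgraph; nodes outside that
    component are filled i.i.d. (with a warning when a module is
    disconnected).
    """
    modules = part.modules()
    labels = sorted(modules, key=str)
    kappa = len(labels)
    if len(means) != kappa:
        raise ValueError(f"need {kappa} means, got {len(means)}")
    if not 0 <= n_assortative <= kappa:
        raise ValueError("n_assortative must lie in [0, kappa]")
    lo, hi = r_band
    if not 0 < lo <= hi < 1:
        raise ValueError("r_band must satisfy 0 < lo <= hi < 1")
    rng = np.random.default_rng(seed)
    assort = np.zeros(kappa, dtype=bool)
    assort[rng.permutation(kappa)[:n_assortative]] = True

    out: dict[str, float] = {}
    for j, lab in enumerate(labels):
        members = modules[lab]
        dist = ValueDistribution(mu=means[j], sigma2=sigma2)
        sign = 1.0 if assort[j] else -1.0
        r_target = sign * rng.uniform(lo, hi)
        sub = net.subgraph(members)
        sd = math.sqrt(sigma2)
        if sub.n_edges == 0:
            logger.warning("module %r has no internal edges; values i.i.d.", lab)
            for v in members:
                out[v] = float(rng.normal(dist.mu, sd))
            continue
        comp = largest_component(sub)
        if comp.n_nodes < sub.n_nodes:
            logger.warning(
                "module %r disconnected (%d of %d nodes in largest component); "
                "stragglers filled i.i.d.",
                lab,
                comp.n_nodes,
                sub.n_nodes,
            )
        mseed = int(rng.integers(2**31))
        vals = assign_values_mcmc(
            comp,
            dist,
            MCMCConfig(
                r_target=r_target,
                beta_tol=beta_tol,
                max_proposals=max_proposals,
                seed=mseed,
            ),
        )
        for v in members:
            out[v] = vals[v] if comp.has_node(v) else float(rng.normal(dist.mu, sd))
    return NodeValues(out)


def permute_noise(
    x: NodeValues,
    fraction: float,
    within: Partition | None = None,
    seed: int | None = None,
) -> tuple[NodeValues, list[str]]:
    """Permute the values of a uniformly random fraction of nodes.

    Exactly ⌊fraction·n⌋ nodes are selected without replacement (per module
    when ``within`` is given, ⌊fraction·n_module⌋ each) and their values
    replaced by a uniformly random permutation of themselves. The multiset of
    values is conserved exactly (per module under ``within``).

    Returns the corrupted values and the sorted list of selected node IDs.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = dict(x.values)
    selected: list[str] = []
    if within is None:
        pools = [sorted(x.values)]
    else:
        pools = [sorted(m) for _, m in sorted(within.modules().items(), key=lambda kv: str(kv[0]))]
    for pool in pools:
        n_sel = int(math.floor(fraction * len(pool)))
        if n_sel == 0:
            continue
        chosen = [pool[i] for i in rng.choice(len(pool), size=n_sel, replace=False)]
        vals = np.array([out[v] for v in chosen])
        perm = rng.permutation(n_sel)
        for v, val in zip(chosen, vals[perm]):
            out[v] = float(val)
        selected.extend(chosen)
    return NodeValues(out), sorted(selected)


def rewire_edges(net: Network, fraction: float, seed: int | None = None) -> Network:
    """Replace a uniformly random fraction of edges with uniformly random new
    node pairs, rejecting self-loops and duplicates. Preserves the node set
    and the edge count exactly."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = net.edges()
    m = len(edges)
    n_rw = int(math.floor(fraction * m))
    if n_rw == 0:
        return Network.from_edges(edges, nodes=net.node_ids)
    drop_idx = set(rng.choice(m, size=n_rw, replace=False).tolist())
    kept = {e for i, e in enumerate(edges) if i not in drop_idx}
    nodes = list(net.node_ids)
    n = len(nodes)
    added = 0
    rejections = 0
    while added < n_rw:
        if rejections > _MAX_REWIRE_REJECTIONS:
            raise RuntimeError(
                "could not place replacement edges without multi-edges "
                f"after {_MAX_REWIRE_REJECTIONS} rejections (graph too dense)"
            )
        i, j = rng.integers(n, size=2)
        if i == j:
            rejections += 1
            continue
        u, v = nodes[i], nodes[j]
        e = (min(u, v), max(u, v))
        if e in kept:
            rejections += 1
            continue
        kept.add(e)
        added += 1
    return Network.from_edges(sorted(kept), nodes=net.node_ids)
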