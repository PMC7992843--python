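"""Diffusion-kernel denoising baselines and entropy-based parameter selection.

Two global operators serve as comparison methods for the local network
filters: the Laplacian exponential heat kernel S_beta = exp(-beta * L)
(symmetric, doubly stochastic), and the personalized-PageRank kernel
K_alpha = (1 - alpha) (I - alpha * B)^(-1) with B the column-degree-normalized
adjacency (columns of K are restart-alpha random-walk stationary weights and
sum to 1). Denoising is the plain matrix-vector product with the noisy data.

Both operators have one smoothing parameter. ``select_smoothing`` picks it
data-adaptively: denoise a panel at each candidate, embed the samples with a
2-component PCA, bin them into a 4x4 occupancy grid, and keep the smallest
candidate maximizing the Shannon entropy of the occupancy distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.decomposition import PCA

from .netcore import Network, NodeValues

__all__ = [
    "KernelMatrix",
    "laplacian_kernel",
    "ppr_kernel",
    "apply_kernel",
    "select_smoothing",
    "DEFAULT_PARAM_GRID",
]

DEFAULT_PARAM_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))

# above this size the dense matrix exponential is replaced by expm_multiply
_DENSE_EXPM_LIMIT = 2000


@dataclass
class KernelMatrix:
    """An n x n denoising operator in canonical node order.

    For the ``ppr`` family the personalized-PageRank weight vector of node i
    is the i-th *column* of the kernel (columns sum to 1), so denoising node
    i combines values along that column: x_hat = K^T x. The Laplacian
    exponential kernel is symmetric, so its orientation is immaterial.
    """

    matrix: np.ndarray
    family: str  # "laplacian_exp" | "ppr"
    param: float
    node_ids: tuple[str, ...]

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.family == "ppr":
            return self.matrix.T @ x
        return self.matrix @ x


def laplacian_kernel(net: Network, beta: float) -> KernelMatrix:
    """Laplacian exponential diffusion kernel S_beta = exp(-beta (D - A)).

    Symmetric and doubly stochastic (rows and columns sum to 1), since the
    Laplacian annihilates the constant vector.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    a = net.adjacency()
    lap = sp.diags(net.degrees()) - a
    n = net.n_nodes
    if n <= _DENSE_EXPM_LIMIT:
        mat = scipy.linalg.expm(-beta * lap.toarray())
    else:
        mat = spla.expm_multiply(-beta * lap.tocsc(), np.eye(n))
    return KernelMatrix(np.asarray(mat), "laplacian_exp", beta, net.node_ids)


def ppr_kernel(net: Network, alpha_restart: float) -> KernelMatrix:
    """Personalized-PageRank kernel K = (1 - alpha) (I - alpha B)^(-1).

    B_ij = 1/k_j when (i, j) is an edge, so B is column-stochastic and the
    columns of K sum to 1. Requires 0 <= alpha < 1 and no isolated nodes.
    """
    if not 0.0 <= alpha_restart < 1.0:
        raise ValueError("alpha_restart must lie in [0, 1)")
    k = net.degrees()
    if np.any(k == 0):
        raise ValueError("ppr kernel undefined with isolated (degree-0) nodes")
    b = net.adjacency().toarray() / k[np.newaxis, :]
    n = net.n_nodes
    mat = (1.0 - alpha_restart) * scipy.linalg.inv(
        np.eye(n) - alpha_restart * b
    )
    return KernelMatrix(mat, "ppr", alpha_restart, net.node_ids)


def apply_kernel(kernel: KernelMatrix, x: NodeValues) -> NodeValues:
    """Denoise node values by the kernel matrix-vector product."""
    xv = np.array([x[v] for v in kernel.node_ids], dtype=float)
    out = kernel.apply(xv)
    return NodeValues(dict(zip(kernel.node_ids, out)))


def grid_entropy(points: np.ndarray, bins: int = 4) -> float:
    """Shannon entropy (nats) of the occupancy of an equal-width 2-D grid
    spanning [min, max] on each coordinate; the last bin is right-closed so
    the maximum point is counted. 0*log 0 := 0."""
    pts = np.asarray(points, dtype=float)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    p = counts.ravel() / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def select_smoothing(
    net: Network,
    data: np.ndarray,
    family: str,
    grid: tuple[float, ...] = DEFAULT_PARAM_GRID,
    bins: int = 4,
) -> float:
    """Choose the smallest smoothing parameter maximizing embedding entropy.

    ``data`` is an entities x samples matrix whose rows align with the
    network's canonical node order. For each candidate parameter every sample
    column is denoised, the samples are embedded by 2-component (centered,
    unscaled) PCA, binned on a ``bins`` x ``bins`` grid, and scored by the
    Shannon entropy of cell occupancy. Ties go to the smallest parameter.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be an entities x samples matrix, >= 2 samples")
    if not grid:
        raise ValueError("parameter grid must be nonempty")
    make = {"laplacian_exp": laplacian_kernel, "ppr": ppr_kernel}
    if family not in make:
        raise ValueError(f"unknown kernel family {family!r}")
    entropies = []
    for param in sorted(grid):
        kernel = make[family](net, param)
        denoised = np.column_stack(
            [kernel.apply(data[:, j]) for j in range(data.shape[1])]
        )
        emb = PCA(n_components=2).fit_transform(denoised.T)
        if np.allclose(emb, emb[0]):
            entropies.append(0.0)
        else:
            entropies.append(grid_entropy(emb, bins=bins))
    entropies = np.asarray(entropies)
    best = np.flatnonzero(entropies >= entropies.max() - 1e-12)[0]
    return float(sorted(grid)[best])
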