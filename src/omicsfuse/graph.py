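"""Adaptive probability graphs and the normalized adjacency for smoothing.

Each row of the adaptive graph solves a simplex-constrained quadratic
program trading pairwise squared distances against an RBF guidance matrix:

    min_{a_i >= 0, a_i^T 1 = 1}  sum_j d_ij a_ij + ||a_i - p_i||^2

which, completing the square, is the Euclidean projection of
``p_i - d_i / 2`` onto the probability simplex. The diagonal is excluded
(self-similarity would absorb all mass and yield the trivial solution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist


@dataclass
class ProbabilityGraph:
    """Row-stochastic soft-neighbor matrix with its guidance and degrees."""

    A: np.ndarray          # N x N, rows on the simplex, zero diagonal
    P: np.ndarray          # RBF guidance matrix
    degrees: np.ndarray    # symmetrized row sums (centrality signal)
    sigma: float           # RBF bandwidth actually used


@dataclass
class NormalizedAdjacency:
    """Symmetrically normalized adjacency with self-loops, D^{-1/2} A* D^{-1/2}."""

    A_tilde: np.ndarray
    self_loops: bool = True


def _sq_dists(Z: np.ndarray) -> np.ndarray:
    d = squareform(pdist(Z, metric="sqeuclidean"))
    return d


def rbf_guidance(Z: np.ndarray, sigma: float | None = None) -> np.ndarray:
    """Gaussian-kernel similarity, P_ij = exp(-||z_i - z_j||^2 / (2 sigma^2)).

    Without an explicit bandwidth the median heuristic over pairwise
    Euclidean distances is used; identical points (median 0) fall back to
    sigma = 1 with a warning.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    d2 = _sq_dists(Z)
    if sigma is None:
        med = float(np.median(np.sqrt(d2[np.triu_indices_from(d2, k=1)])))
        if med <= 0:
            warnings.warn("all points identical; RBF bandwidth fell back to 1.0")
            sigma = 1.0
        else:
            sigma = med
    elif sigma <= 0:
        raise ValueError("sigma must be positive")
    P = np.exp(-d2 / (2.0 * sigma * sigma))
    return P


def rbf_bandwidth(Z: np.ndarray) -> float:
    """The median-heuristic bandwidth rbf_guidance would pick (1.0 fallback)."""
    Z = np.asarray(Z, dtype=np.float64)
    d2 = _sq_dists(Z)
    med = float(np.median(np.sqrt(d2[np.triu_indices_from(d2, k=1)])))
    return med if med > 0 else 1.0


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {a >= 0, sum a = 1} (sort-based algorithm)."""
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("v must be a non-empty 1-D vector")
    return _project_rows(v[None, :])[0]


def _project_rows(V: np.ndarray) -> np.ndarray:
    """Row-wise simplex projection, vectorized."""
    n = V.shape[1]
    U = -np.sort(-V, axis=1)                      # descending
    css = np.cumsum(U, axis=1) - 1.0
    j = np.arange(1, n + 1)
    cond = U - css / j > 0
    rho = cond.shape[1] - 1 - np.argmax(cond[:, ::-1], axis=1)  # last True index
    tau = css[np.arange(V.shape[0]), rho] / (rho + 1)
    return np.maximum(V - tau[:, None], 0.0)


def solve_adaptive_graph(Z: np.ndarray, P: np.ndarray) -> ProbabilityGraph:
    """Solve the per-row simplex QP to obtain the adaptive probability graph."""
    Z = np.asarray(Z, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    n = Z.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to build a neighbor graph")
    if P.shape != (n, n):
        raise ValueError(f"guidance matrix shape {P.shape} != ({n}, {n})")
    d2 = _sq_dists(Z)
    # target of the projection, self-column removed per row
    off = ~np.eye(n, dtype=bool)
    V = (P - d2 / 2.0)[off].reshape(n, n - 1)
    rows = _project_rows(V)
    A = np.zeros((n, n))
    A[off] = rows.ravel()
    degrees = node_degrees(A)
    return ProbabilityGraph(A=A, P=P, degrees=degrees, sigma=float("nan"))


def build_adaptive_graph(Z: np.ndarray, sigma: float | None = None) -> ProbabilityGraph:
    """RBF guidance then the adaptive-graph QP, in bandwidth-standardized units.

    The row objective adds a unitless guidance term to squared distances in
    embedding units; solved on raw coordinates the distance term dominates and
    every row collapses to a single nearest neighbor — a hard 0/1 graph, the
    opposite of the soft probability graph the construction is meant to give.
    Solving on Z / sigma (the same bandwidth the RBF kernel uses, so
    P = exp(-d_s^2 / 2) in the standardized metric) keeps the two terms
    commensurate and the rows genuinely soft.
    """
    used = float(sigma) if sigma is not None else rbf_bandwidth(Z)
    P = rbf_guidance(Z, sigma=used)
    g = solve_adaptive_graph(np.asarray(Z, dtype=np.float64) / used, P)
    return ProbabilityGraph(A=g.A, P=P, degrees=g.degrees, sigma=used)


def node_degrees(A: np.ndarray) -> np.ndarray:
    """Degrees on the symmetrized graph, deg_i = sum_j (A + A^T)_ij / 2.

    Row sums of the row-stochastic A itself are identically 1 and carry no
    centrality signal; symmetrizing lets cells that many others choose as a
    neighbor accumulate degree above 1.
    """
    A = np.asarray(A, dtype=np.float64)
    return ((A + A.T) / 2.0).sum(axis=1)


def normalized_adjacency(A_f: np.ndarray) -> NormalizedAdjacency:
    """Self-looped, symmetrically normalized adjacency D^{-1/2} A* D^{-1/2}."""
    A_f = np.asarray(A_f, dtype=np.float64)
    n = A_f.shape[0]
    if A_f.shape != (n, n):
        raise ValueError("A_f must be square")
    if (A_f < 0).any():
        raise ValueError("A_f must be non-negative")
    sym = (A_f + A_f.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    A_star = sym + np.eye(n)
    deg = A_star.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    A_tilde = inv_sqrt[:, None] * A_star * inv_sqrt[None, :]
    return NormalizedAdjacency(A_tilde=A_tilde, self_loops=True)
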