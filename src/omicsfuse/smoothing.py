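"""Adaptive-depth graph-convolution smoothing and final clustering.

Repeated multiplication by the normalized adjacency is Laplacian smoothing:
it contracts each cell's features toward its soft neighborhood. Too few
rounds under-smooth, too many collapse clusters (over-smoothing). The depth
is chosen adaptively by monitoring the intra-cluster compactness

    xi = (1/|C|) sum_i (1/|c_i|^2) sum_{x_a, x_b in c_i} ||x_a - x_b||^2

of a K-means partition recomputed after every propagation step, stopping at
the first step where xi increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .graph import NormalizedAdjacency


@dataclass
class SmoothingTrace:
    """The xi sequence, the depth selected, and whether the stop rule fired."""

    xi_values: list
    selected_t: int
    max_layers: int
    stopped_early: bool


@dataclass
class ClusterResult:
    labels: np.ndarray
    embedding: np.ndarray
    trace: SmoothingTrace | None = None
    nmi: float | None = None
    ari: float | None = None
    selected_t: int | None = None
    variant: str = "full"


def gcn_propagate(X_l: np.ndarray, A_tilde: NormalizedAdjacency,
                  W_l: np.ndarray | None = None) -> np.ndarray:
    """One graph-convolution step.

    Parameter-free default: X^{l+1} = A_tilde X^l (identity weights, linear
    activation — pure Laplacian smoothing). With ``W_l`` given, the trainable
    form ReLU(A_tilde X^l W^l) is used.
    """
    X_l = np.asarray(X_l, dtype=np.float64)
    At = A_tilde.A_tilde if isinstance(A_tilde, NormalizedAdjacency) else np.asarray(A_tilde)
    if At.shape[1] != X_l.shape[0]:
        raise ValueError(f"adjacency {At.shape} does not match features {X_l.shape}")
    out = At @ X_l
    if W_l is not None:
        W_l = np.asarray(W_l, dtype=np.float64)
        if W_l.shape[0] != X_l.shape[1]:
            raise ValueError("weight matrix width mismatch")
        out = np.maximum(out @ W_l, 0.0)
    return out


def mse_loss(pred, target) -> float:
    """Mean squared error over all entries."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((p - t) ** 2))


def intra_cluster_measure(X: np.ndarray, labels: np.ndarray) -> float:
    """Average, over clusters, of the ordered-pair mean squared distance.

    For cluster c with members x_a: (1/|c|^2) sum_{a,b} ||x_a - x_b||^2,
    then averaged over clusters; pairs include a = b (contributing zero),
    matching the 1/|c|^2 normalizer.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length mismatch")
    uniq = np.unique(labels)
    if uniq.size == 0:
        raise ValueError("no clusters")
    total = 0.0
    for c in uniq:
        pts = X[labels == c]
        m = pts.shape[0]
        # sum over ordered pairs ||a-b||^2 = 2m * sum||a||^2 - 2||sum a||^2
        sq = (pts**2).sum()
        s = pts.sum(axis=0)
        total += (2.0 * m * sq - 2.0 * (s**2).sum()) / (m * m)
    return float(total / uniq.size)


def cluster(X: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """K-means labels (n_init=20, fixed seed)."""
    X = np.asarray(X, dtype=np.float64)
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds number of points {X.shape[0]}")
    km = KMeans(n_clusters=K, n_init=20, random_state=seed)
    return km.fit_predict(X)


def adaptive_smooth(Z: np.ndarray, A_tilde: NormalizedAdjacency, K: int,
                    max_layers: int = 8, seed: int = 0
                    ) -> tuple[np.ndarray, SmoothingTrace]:
    """Propagate until the first xi increase; return the embedding at depth t.

    xi^(t) is the intra-cluster measure of a seeded K-means partition of the
    depth-t embedding. A strict increase xi^(t+1) > xi^(t) stops the
    iteration and depth t is kept; ties continue.
    """
    if max_layers < 1:
        raise ValueError("max_layers must be >= 1")
    Z = np.asarray(Z, dtype=np.float64)
    xs = [Z]
    xi = [intra_cluster_measure(Z, cluster(Z, K, seed))]
    selected_t, stopped = max_layers, False
    for t in range(max_layers):
        X_next = gcn_propagate(xs[-1], A_tilde)
        if not np.isfinite(X_next).all():
            raise FloatingPointError(f"non-finite features at depth {t + 1}")
        xs.append(X_next)
        xi.append(intra_cluster_measure(X_next, cluster(X_next, K, seed)))
        if xi[-1] > xi[-2]:
            selected_t, stopped = t, True
            break
    trace = SmoothingTrace(xi_values=xi, selected_t=selected_t,
                           max_layers=max_layers, stopped_early=stopped)
    return xs[selected_t], trace


def evaluate(labels: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(NMI, ARI) between a clustering and reference labels."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape[0] != truth.shape[0]:
        raise ValueError("label vectors differ in length")
    nmi = normalized_mutual_info_score(truth, labels, average_method="arithmetic")
    ari = adjusted_rand_score(truth, labels)
    return float(nmi), float(ari)
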