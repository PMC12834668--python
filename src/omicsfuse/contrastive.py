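"""Multi-subspace encoder and the two mutual-information estimators.

Each view's embedding is split into ``p`` subspaces by attention over
learned query vectors (with a degree-structure bias). Cross-view agreement
is rewarded through a Jensen-Shannon lower bound on mutual information with
a dot-product discriminator; within-view redundancy between subspaces is
penalized through the CLUB upper bound with a fixed Gaussian conditional
N(u^(l) | u^(k), beta^{-1} I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class MSEncoderParams:
    """Parameters of the multi-subspace encoder for one view.

    ``W_S`` maps the diagonal degree matrix to one structural score per
    subspace (one row per cell). Each subspace has its own value projection
    ``B[k]`` of shape (d_V, d_sub); the attention weight scales the shared
    value embedding before projection.
    """

    W_K: object            # d x d_K
    W_V: object            # d x d_V
    Q: object              # d_K x p
    W_S: object            # N x p
    B: list                # p matrices, d_V x d_sub
    alpha: float = 1.0
    p: int = 3
    d_sub: int = 10


@dataclass
class SubspaceSet:
    """Per-view subspace embeddings (N x p x d_sub) and the attention that made them."""

    embeddings: np.ndarray
    att: np.ndarray
    view: str = "u"

    @property
    def p(self) -> int:
        return self.embeddings.shape[1]

    @property
    def d_sub(self) -> int:
        return self.embeddings.shape[2]

    def subspace(self, k: int) -> np.ndarray:
        return self.embeddings[:, k, :]

    def flatten(self) -> np.ndarray:
        n = self.embeddings.shape[0]
        return self.embeddings.reshape(n, -1)


def init_msencoder(d: int, n_cells: int, p: int, rng: np.random.Generator,
                   d_key: int | None = None, alpha: float = 1.0,
                   trainable: bool = True) -> MSEncoderParams:
    """Initialize one view's MSEncoder; requires p * d_sub = d / 2."""
    if d % (2 * p) != 0:
        raise ValueError(f"d={d} must be divisible by 2p={2 * p} "
                         "(each view flattens to d/2)")
    d_sub = d // (2 * p)
    d_key = d_key if d_key is not None else d
    d_val = d

    def glorot(fi, fo):
        lim = np.sqrt(6.0 / (fi + fo))
        return Tensor(rng.uniform(-lim, lim, size=(fi, fo)), requires_grad=trainable)

    return MSEncoderParams(
        W_K=glorot(d, d_key),
        W_V=glorot(d, d_val),
        Q=glorot(d_key, p),
        W_S=glorot(n_cells, p),
        B=[glorot(d_val, d_sub) for _ in range(p)],
        alpha=alpha,
        p=p,
        d_sub=d_sub,
    )


def _msencoder_subspaces(Z, degrees, params: MSEncoderParams):
    """Generic forward: returns (att, [subspace_k]) on arrays or Tensors."""
    degrees = np.asarray(degrees, dtype=np.float64)
    K = ad.matmul(Z, params.W_K)
    V = ad.matmul(Z, params.W_V)
    # S = D W_S with D the diagonal degree matrix: row i of W_S scaled by deg_i
    S = params.W_S * degrees[:, None] if isinstance(params.W_S, Tensor) \
        else np.asarray(params.W_S) * degrees[:, None]
    scores = ad.matmul(K, params.Q) + params.alpha * S
    att = ad.softmax_rows(scores)                       # N x p
    subspaces = []
    for k in range(params.p):
        a_k = att[:, k : k + 1] if isinstance(att, Tensor) else att[:, k : k + 1]
        subspaces.append(ad.matmul(a_k * V, params.B[k]))
    return att, subspaces


def msencoder_forward(Z: np.ndarray, degrees_diag: np.ndarray,
                      params: MSEncoderParams, view: str = "u") -> SubspaceSet:
    """Array-facing MSEncoder forward pass.

    ``degrees_diag`` may be the N x N diagonal degree matrix or the length-N
    degree vector.
    """
    degrees_diag = np.asarray(degrees_diag, dtype=np.float64)
    degrees = np.diag(degrees_diag) if degrees_diag.ndim == 2 else degrees_diag
    d = np.asarray(Z).shape[1]
    if params.p * params.d_sub * 2 != d:
        raise ValueError(
            f"p*d_sub={params.p * params.d_sub} must equal d/2={d // 2}")
    att, subs = _msencoder_subspaces(np.asarray(Z, dtype=np.float64),
                                     degrees, params)
    att = att.data if isinstance(att, Tensor) else att
    subs = [s.data if isinstance(s, Tensor) else s for s in subs]
    emb = np.stack(subs, axis=1)
    return SubspaceSet(embeddings=emb, att=att, view=view)


def row_normalize(x):
    """Project rows onto the unit sphere (generic over arrays/tensors).

    The MI estimators are evaluated on unit-norm rows during training: both
    the JS bound and CLUB scale with the square of the embedding norm, so
    without this the within-view CLUB term can be driven to -inf simply by
    inflating magnitudes.
    """
    n2 = ad.summ(x * x, axis=1, keepdims=True)
    return x / ad.sqrt(n2 + 1e-12)


def random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform-ish permutation with no fixed points (rejection sampling)."""
    if n < 2:
        raise ValueError("a derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def _js_mi(u, r, perm: np.ndarray):
    """Generic JS lower bound; negatives are rows of r permuted by ``perm``."""
    pos_logits = ad.summ(u * r, axis=1)
    neg_logits = ad.summ(u * ad.take_rows(r, perm), axis=1)
    pos_term = ad.mean(-ad.softplus(-pos_logits))
    neg_term = ad.mean(ad.softplus(neg_logits))
    return pos_term - neg_term


def js_mi(pos_u: np.ndarray, pos_r: np.ndarray,
          neg_pairing: np.ndarray | None = None, seed: int = 0) -> float:
    """Jensen-Shannon MI lower bound with the dot-product discriminator.

    Value is E_pos[-SP(-<u_i, r_i>)] - E_neg[SP(<u_i, r_pi(i)>)], always <= 0,
    approaching 0 only when positives and negatives are perfectly separated.
    """
    pos_u = np.asarray(pos_u, dtype=np.float64)
    pos_r = np.asarray(pos_r, dtype=np.float64)
    if pos_u.shape != pos_r.shape:
        raise ValueError("view shapes differ")
    n = pos_u.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells for negative pairs")
    if neg_pairing is None:
        neg_pairing = random_derangement(n, np.random.default_rng(seed))
    neg_pairing = np.asarray(neg_pairing, dtype=int)
    if np.any(np.sort(neg_pairing) != np.arange(n)):
        raise ValueError("neg_pairing is not a permutation")
    if np.any(neg_pairing == np.arange(n)):
        raise ValueError("neg_pairing must have no fixed points")
    return float(_js_mi(pos_u, pos_r, neg_pairing))


def _club(u_k, u_l, beta: float):
    """Generic CLUB estimate under N(u_l | u_k, beta^{-1} I)."""
    data_k = u_k.data if isinstance(u_k, Tensor) else np.asarray(u_k)
    n = data_k.shape[0]
    sq_k = ad.summ(u_k * u_k, axis=1)
    sq_l = ad.summ(u_l * u_l, axis=1)
    G = ad.matmul(u_k, u_l.T if isinstance(u_l, Tensor) else np.asarray(u_l).T)
    if isinstance(sq_k, Tensor):
        D2 = sq_k.reshape(n, 1) + sq_l.reshape(1, n) - 2.0 * G
    else:
        D2 = sq_k[:, None] + sq_l[None, :] - 2.0 * G
    eye = np.eye(n)
    diag_sum = ad.summ(D2 * eye)
    pos = diag_sum / float(n)                               # E_i ||u_l_i - u_k_i||^2
    if n < 2:
        return 0.0 * pos
    neg = (ad.summ(D2) - diag_sum) / float(n * (n - 1))     # E_{i != j}
    return (beta / 2.0) * (neg - pos)


def club_upper_bound(u_k: np.ndarray, u_l: np.ndarray, beta: float = 1.0) -> float:
    """CLUB mutual-information upper bound between two subspaces of one view."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    u_k = np.asarray(u_k, dtype=np.float64)
    u_l = np.asarray(u_l, dtype=np.float64)
    if u_k.shape != u_l.shape:
        raise ValueError("subspace shapes differ")
    return float(_club(u_k, u_l, beta))


def _contrastive(subs_u: list, subs_r: list, gamma: float, beta: float,
                 perm: np.ndarray):
    """Generic combined loss: -sum_k JS(u_k, r_k) + gamma sum_{k<l} CLUB(u_k, u_l)."""
    p = len(subs_u)
    loss = None
    for k in range(p):
        term = -_js_mi(subs_u[k], subs_r[k], perm)
        loss = term if loss is None else loss + term
    if gamma > 0:
        for k in range(p):
            for l in range(k + 1, p):
                loss = loss + gamma * _club(subs_u[k], subs_u[l], beta)
    return loss


def contrastive_loss(U: SubspaceSet, R: SubspaceSet, gamma: float = 1.0,
                     beta: float = 1.0, seed: int = 0) -> float:
    """The multi-subspace contrastive objective, to be minimized."""
    if U.p != R.p or U.d_sub != R.d_sub or U.embeddings.shape != R.embeddings.shape:
        raise ValueError("subspace sets are not conformable")
    if beta <= 0:
        raise ValueError("beta must be positive")
    n = U.embeddings.shape[0]
    perm = random_derangement(n, np.random.default_rng(seed))
    subs_u = [U.subspace(k) for k in range(U.p)]
    subs_r = [R.subspace(k) for k in range(R.p)]
    return float(_contrastive(subs_u, subs_r, gamma, beta, perm))


def concat_views(U: SubspaceSet, R: SubspaceSet) -> np.ndarray:
    """Z^{ra} = [flatten(U) | flatten(R)], U subspaces first, then R."""
    fu, fr = U.flatten(), R.flatten()
    if fu.shape != fr.shape:
        raise ValueError("views flatten to different widths")
    return np.concatenate([fu, fr], axis=1)
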