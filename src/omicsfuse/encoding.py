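"""Omics-specific encoders, degree-centrality enhancement, self-attention fusion.

Every forward function here is written against the generic ops in
:mod:`omicsfuse.autodiff`, so it evaluates identically on plain arrays (the
public API) and on autodiff tensors (inside training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class EncoderParams:
    """A fully connected encoder: weights/biases per layer, hidden activation.

    The activation is applied after every layer except the last, so a
    single-layer encoder is linear.
    """

    weights: list          # list of (W, b) pairs; arrays or Tensors
    activation: str = "elu"
    modality: str = "rna"

    @property
    def widths(self) -> list[int]:
        ws = [w.shape[0] if not isinstance(w, Tensor) else w.data.shape[0]
              for w, _ in self.weights]
        last = self.weights[-1][0]
        out = last.data.shape[1] if isinstance(last, Tensor) else last.shape[1]
        return ws + [out]


def init_encoder(widths: list[int], rng: np.random.Generator,
                 activation: str = "elu", modality: str = "rna",
                 trainable: bool = True) -> EncoderParams:
    """Glorot-initialized encoder with the given layer widths (D, ..., d)."""
    weights = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((Tensor(W, requires_grad=trainable),
                        Tensor(b, requires_grad=trainable)))
    return EncoderParams(weights=weights, activation=activation, modality=modality)


_ACTIVATIONS = {
    "relu": ad.relu,
    "elu": ad.elu,
    "identity": lambda x: x,
}


def encode(X, params: EncoderParams):
    """Forward pass X -> Z through the encoder MLP."""
    act = _ACTIVATIONS[params.activation]
    h = X
    first_w = params.weights[0][0]
    d_in = first_w.data.shape[0] if isinstance(first_w, Tensor) else first_w.shape[0]
    x_cols = X.data.shape[1] if isinstance(X, Tensor) else np.asarray(X).shape[1]
    if x_cols != d_in:
        raise ValueError(f"input width {x_cols} != encoder first layer {d_in}")
    for i, (W, b) in enumerate(params.weights):
        h = ad.matmul(h, W) + b
        if i < len(params.weights) - 1:
            h = act(h)
    return h


@dataclass
class CentralityParams:
    """One learnable vector per modality; softplus keeps it positive."""

    c_raw: object  # length-d array or Tensor

    def effective(self):
        return ad.softplus(self.c_raw)


def init_centrality(d: int, rng: np.random.Generator,
                    trainable: bool = True) -> CentralityParams:
    # softplus(0.5413) ~= 1, so the effective vector starts near ones
    c0 = rng.normal(0.5413, 0.05, size=d)
    return CentralityParams(c_raw=Tensor(c0, requires_grad=trainable))


def centrality_encode(Z, degrees, params: CentralityParams):
    """z_i + log(1 + C * deg_i): the degree scales a learnable vector.

    C > 0 via softplus, so the enhancement is zero exactly when deg_i = 0 and
    monotone increasing in the degree.
    """
    degrees = np.asarray(degrees, dtype=np.float64)
    if (degrees < 0).any():
        raise ValueError("degrees must be non-negative")
    C = params.effective()
    deg_col = degrees[:, None]
    return Z + ad.log1p(C * deg_col)


@dataclass
class EnhancedEmbedding:
    """Raw, centrality-enhanced and attention-fused embeddings of one omics."""

    Z: np.ndarray
    Z_hat: np.ndarray
    Att: np.ndarray
    Z_tilde: np.ndarray


def self_attention_enhance(Z_hat):
    """Full self-attention: Att = row-softmax(Z_hat Z_hat^T / sqrt(d)).

    Returns (Att, Z_tilde) with Z_tilde = Att @ Z_hat; each output row is a
    convex combination of input rows.
    """
    data = Z_hat.data if isinstance(Z_hat, Tensor) else np.asarray(Z_hat)
    if not np.isfinite(data).all():
        raise ValueError("Z_hat contains non-finite entries")
    d = data.shape[1]
    scores = ad.matmul(Z_hat, Z_hat.T if isinstance(Z_hat, Tensor) else data.T)
    scores = scores / float(np.sqrt(d))
    Att = ad.softmax_rows(scores)
    Z_tilde = ad.matmul(Att, Z_hat)
    return Att, Z_tilde
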