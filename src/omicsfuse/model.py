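"""Fusion of the learned embeddings, generative decoding and joint training.

The fused embedding Z = Z^{ra} + lambda_r * Zt^r + lambda_a * Zt^a feeds two
decoders: a zero-inflated negative binomial (ZINB) decoder for RNA counts
(dropout probability Pi, mean M_r, dispersion Theta) and a Bernoulli decoder
for binarized accessibility (mean M_a). The overall objective is

    L1 = ZINB-NLL(X^r) + alpha_1 * CE(X^a, M_a) + alpha_2 * L_contrastive

minimized with Adam in two stages: per-omics autoencoder pretraining, then
joint training of everything with the adaptive graphs built once from the
pretrained embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .contrastive import (
    MSEncoderParams,
    _contrastive,
    _msencoder_subspaces,
    init_msencoder,
    random_derangement,
    row_normalize,
)
from .encoding import (
    CentralityParams,
    EncoderParams,
    centrality_encode,
    encode,
    init_centrality,
    init_encoder,
    self_attention_enhance,
)
from .graph import ProbabilityGraph, build_adaptive_graph
from .io import PairedOmics, binarize_atac, normalize_rna

log = logging.getLogger(__name__)

_EXP_CLAMP = (-11.5, 13.8)  # exp range ~ [1e-5, 1e6]


@dataclass
class FusionWeights:
    lambda_r: float = 0.1
    lambda_a: float = 0.1

    def __post_init__(self):
        if self.lambda_r < 0 or self.lambda_a < 0:
            raise ValueError("fusion weights must be non-negative")


@dataclass
class LossWeights:
    alpha_1: float = 0.1   # Bernoulli term
    alpha_2: float = 1.0   # contrastive term
    gamma: float = 1.0     # within-view CLUB weight inside the contrastive term

    def __post_init__(self):
        for v in (self.alpha_1, self.alpha_2, self.gamma):
            if not np.isfinite(v) or v < 0:
                raise ValueError("loss weights must be finite and non-negative")


@dataclass
class ZINBParams:
    """Decoder outputs: Pi, M_r, Theta for RNA and the Bernoulli mean M_a."""

    Pi: np.ndarray
    M_r: np.ndarray
    Theta: np.ndarray
    M_a: np.ndarray | None = None


def fuse(Z_ra, Z_tilde_r, Z_tilde_a, w: FusionWeights):
    """Z = Z^{ra} + lambda_r Zt^r + lambda_a Zt^a (elementwise weighted sum)."""
    shapes = [x.data.shape if isinstance(x, Tensor) else np.asarray(x).shape
              for x in (Z_ra, Z_tilde_r, Z_tilde_a)]
    if len(set(shapes)) != 1:
        raise ValueError(f"shape mismatch among fusion inputs: {shapes}")
    out = Z_ra
    if w.lambda_r != 0:
        out = out + w.lambda_r * Z_tilde_r
    if w.lambda_a != 0:
        out = out + w.lambda_a * Z_tilde_a
    return out


def zinb_nll(X_r, params: ZINBParams):
    """Mean negative log-likelihood of counts under the ZINB mixture.

    NB pmf (with its 1/x! normalizer) is evaluated through log-gamma; the
    two mixture branches at x = 0 are combined with log-sum-exp. ``Pi`` may
    be exactly 0 (pure NB); Pi = 1 is rejected.
    """
    X = X_r.data if isinstance(X_r, Tensor) else np.asarray(X_r, dtype=np.float64)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    pi, mu, theta = params.Pi, params.M_r, params.Theta
    for name, arr, lo_ok in (("Pi", pi, True), ("M_r", mu, False), ("Theta", theta, False)):
        vals = arr.data if isinstance(arr, Tensor) else np.asarray(arr)
        if name == "Pi":
            if (vals < 0).any() or (vals >= 1).any():
                raise ValueError("Pi must lie in [0, 1)")
        elif (vals <= 0).any():
            raise ValueError(f"{name} must be strictly positive")
    with np.errstate(divide="ignore"):
        log_pi = ad.log(pi)
    log_1m_pi = ad.log1p(-1.0 * pi) if isinstance(pi, Tensor) else np.log1p(-pi)
    log_t_tm = ad.log(theta) - ad.log(theta + mu)      # log(theta/(theta+mu))
    log_m_tm = ad.log(mu) - ad.log(theta + mu)         # log(mu/(theta+mu))
    log_nb = (ad.lgamma(X_r + theta) - ad.lgamma(theta) - ad.lgamma(X + 1.0)
              + theta * log_t_tm + X * log_m_tm)
    log_nb0 = theta * log_t_tm
    zero_branch = ad.logaddexp(log_pi, log_1m_pi + log_nb0)
    pos_branch = log_1m_pi + log_nb
    ll = ad.where(X < 0.5, zero_branch, pos_branch)
    out = -ad.mean(ll)
    return out if isinstance(out, Tensor) else float(out)


@dataclass
class DecoderParams:
    """Shared hidden trunk then linear heads (sigmoid / exp output maps)."""

    trunk: tuple            # (W, b)
    heads: dict             # name -> (W, b)
    activation: str = "elu"


def init_zinb_decoder(d: int, hidden: int, d_out: int,
                      rng: np.random.Generator, trainable: bool = True) -> DecoderParams:
    def glorot(fi, fo):
        lim = np.sqrt(6.0 / (fi + fo))
        return (Tensor(rng.uniform(-lim, lim, (fi, fo)), requires_grad=trainable),
                Tensor(np.zeros(fo), requires_grad=trainable))

    return DecoderParams(trunk=glorot(d, hidden),
                         heads={h: glorot(hidden, d_out) for h in ("pi", "mu", "theta")})


def init_bernoulli_decoder(d: int, hidden: int, d_out: int,
                           rng: np.random.Generator, trainable: bool = True) -> DecoderParams:
    def glorot(fi, fo):
        lim = np.sqrt(6.0 / (fi + fo))
        return (Tensor(rng.uniform(-lim, lim, (fi, fo)), requires_grad=trainable),
                Tensor(np.zeros(fo), requires_grad=trainable))

    return DecoderParams(trunk=glorot(d, hidden), heads={"mu_a": glorot(hidden, d_out)})


def _trunk_forward(Z, dec: DecoderParams):
    from .encoding import _ACTIVATIONS

    W, b = dec.trunk
    return _ACTIVATIONS[dec.activation](ad.matmul(Z, W) + b)


def zinb_decode(Z, dec: DecoderParams) -> ZINBParams:
    """Z -> (Pi, M_r, Theta) via sigmoid / clamped-exp heads."""
    h = _trunk_forward(Z, dec)
    raw = {name: ad.matmul(h, W) + b for name, (W, b) in dec.heads.items()}
    # clamp away from {0,1}: float64 sigmoid saturates exactly for |logit| > ~37
    Pi = ad.clip(ad.sigmoid(raw["pi"]), 1e-7, 1.0 - 1e-7)
    M_r = ad.exp(ad.clip(raw["mu"], *_EXP_CLAMP))
    Theta = ad.exp(ad.clip(raw["theta"], *_EXP_CLAMP))
    for name, t in (("pi", Pi), ("mu", M_r), ("theta", Theta)):
        vals = t.data if isinstance(t, Tensor) else t
        if not np.isfinite(vals).all():
            raise FloatingPointError(f"non-finite activations in head {name!r}")
    if not isinstance(Z, Tensor):
        Pi, M_r, Theta = (x.data if isinstance(x, Tensor) else x
                          for x in (Pi, M_r, Theta))
    return ZINBParams(Pi=Pi, M_r=M_r, Theta=Theta)


def bernoulli_decode(Z, dec: DecoderParams):
    """Z -> M_a in (0, 1) via a sigmoid head."""
    h = _trunk_forward(Z, dec)
    W, b = dec.heads["mu_a"]
    M_a = ad.clip(ad.sigmoid(ad.matmul(h, W) + b), 1e-7, 1.0 - 1e-7)
    vals = M_a.data if isinstance(M_a, Tensor) else M_a
    if not np.isfinite(vals).all():
        raise FloatingPointError("non-finite activations in head 'mu_a'")
    return M_a if isinstance(Z, Tensor) else (M_a.data if isinstance(M_a, Tensor) else M_a)


def bernoulli_ce(X_a, M_a):
    """Mean binary cross-entropy, -[x log u + (1-x) log(1-u)]."""
    X = X_a.data if isinstance(X_a, Tensor) else np.asarray(X_a, dtype=np.float64)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("X_a must be binary")
    vals = M_a.data if isinstance(M_a, Tensor) else np.asarray(M_a)
    if (vals <= 0).any() or (vals >= 1).any():
        raise ValueError("M_a must lie strictly in (0, 1)")
    ll = X * ad.log(M_a) + (1.0 - X) * ad.log(1.0 - M_a)
    out = -ad.mean(ll)
    return out if isinstance(out, Tensor) else float(out)


def total_loss(X_r, X_a, params: ZINBParams, contrastive_value, w: LossWeights):
    """L1 = ZINB-NLL + alpha_1 * CE + alpha_2 * contrastive."""
    loss = zinb_nll(X_r, params)
    if w.alpha_1 != 0:
        loss = loss + w.alpha_1 * bernoulli_ce(X_a, params.M_a)
    if w.alpha_2 != 0:
        loss = loss + w.alpha_2 * contrastive_value
    return loss if isinstance(loss, Tensor) else float(loss)


@dataclass
class ModelConfig:
    """Hyperparameters of the full model (defaults are the package reference)."""

    d: int = 60
    hidden: int = 256
    p: int = 3
    alpha: float = 1.0        # degree-bias weight in the MSEncoder attention
    beta: float = 1.0         # CLUB conditional precision
    gamma: float = 1.0        # within-view CLUB weight
    lambda_r: float = 0.1
    lambda_a: float = 0.1
    alpha_1: float = 0.1
    alpha_2: float = 1.0
    lr: float = 1e-3
    pretrain_epochs: int = 60
    joint_epochs: int = 150
    activation: str = "elu"
    use_centrality: bool = True
    use_mscl: bool = True
    rbf_sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.d % (2 * self.p) != 0:
            raise ValueError(f"d={self.d} must be divisible by 2p={2 * self.p}")


@dataclass
class ModelState:
    """Everything needed to re-run the forward pass of a trained model."""

    config: ModelConfig
    enc_r: EncoderParams
    enc_a: EncoderParams
    cent_r: CentralityParams
    cent_a: CentralityParams
    ms_u: MSEncoderParams | None
    ms_r: MSEncoderParams | None
    dec_rna: DecoderParams
    dec_atac: DecoderParams
    graph_r: ProbabilityGraph
    graph_a: ProbabilityGraph
    loss_trace: list = field(default_factory=list)
    trained: bool = False


def _collect_params(*objs):
    out = []
    for obj in objs:
        if obj is None:
            continue
        if isinstance(obj, Tensor):
            out.append(obj)
        elif isinstance(obj, EncoderParams):
            for W, b in obj.weights:
                out.extend([W, b])
        elif isinstance(obj, CentralityParams):
            out.append(obj.c_raw)
        elif isinstance(obj, MSEncoderParams):
            out.extend([obj.W_K, obj.W_V, obj.Q, obj.W_S, *obj.B])
        elif isinstance(obj, DecoderParams):
            out.extend(obj.trunk)
            for W, b in obj.heads.values():
                out.extend([W, b])
    return [p for p in out if isinstance(p, Tensor) and p.requires_grad]


def _forward(state: ModelState, X_rn: np.ndarray, X_ab: np.ndarray,
             perm: np.ndarray | None):
    """One joint forward pass; returns dict of Tensors."""
    cfg = state.config
    Z_r = encode(X_rn, state.enc_r)
    Z_a = encode(X_ab, state.enc_a)
    deg_r, deg_a = state.graph_r.degrees, state.graph_a.degrees
    Zh_r = centrality_encode(Z_r, deg_r, state.cent_r) if cfg.use_centrality else Z_r
    Zh_a = centrality_encode(Z_a, deg_a, state.cent_a) if cfg.use_centrality else Z_a
    _, Zt_r = self_attention_enhance(Zh_r)
    _, Zt_a = self_attention_enhance(Zh_a)

    contra = None
    if cfg.use_mscl:
        _, subs_u = _msencoder_subspaces(Z_r, deg_r, state.ms_u)
        _, subs_r = _msencoder_subspaces(Z_a, deg_a, state.ms_r)
        Z_ra = ad.concat_cols(subs_u + subs_r)
        if perm is not None:
            # MI terms on unit-norm rows: both estimators are scale-sensitive
            contra = _contrastive([row_normalize(s) for s in subs_u],
                                  [row_normalize(s) for s in subs_r],
                                  cfg.gamma, cfg.beta, perm)
    else:
        half = cfg.d // 2
        Z_ra = ad.concat_cols([Z_r[:, :half], Z_a[:, :half]])

    Z = fuse(Z_ra, Zt_r, Zt_a, FusionWeights(cfg.lambda_r, cfg.lambda_a))
    zp = zinb_decode(Z, state.dec_rna)
    zp.M_a = bernoulli_decode(Z, state.dec_atac)
    return {"Z": Z, "zinb": zp, "contra": contra,
            "Z_tilde_r": Zt_r, "Z_tilde_a": Zt_a}


def _pretrain(encoder, decoder, X_in, target, loss_fn, epochs, lr):
    opt = Adam(_collect_params(encoder, decoder), lr=lr)
    for _ in range(epochs):
        opt.zero_grad()
        Z = encode(X_in, encoder)
        loss = loss_fn(Z, target)
        if not np.isfinite(loss.data):
            raise RuntimeError("pretraining diverged (non-finite loss)")
        loss.backward()
        opt.step()


def train(data: PairedOmics, config: ModelConfig | None = None,
          rna_input: np.ndarray | None = None,
          atac_input: np.ndarray | None = None
          ) -> tuple[ModelState, np.ndarray, ZINBParams]:
    """Two-stage training; returns (model state, fused embedding Z, ZINB params).

    Stage 1 pretrains each omics autoencoder on its own likelihood. The
    adaptive probability graphs are then built once from the pretrained
    embeddings, and stage 2 jointly optimizes the full objective.

    ``rna_input`` / ``atac_input`` override the encoder inputs (default:
    normalized RNA and binarized ATAC); the likelihood targets always remain
    the observed raw counts / binary accessibility. The noise-robustness
    harness uses these to feed perturbed inputs.
    """
    cfg = config or ModelConfig()
    rng = np.random.default_rng(cfg.seed)
    X_r = np.asarray(data.rna_counts, dtype=np.float64)
    X_rn = normalize_rna(X_r) if rna_input is None else np.asarray(rna_input, dtype=np.float64)
    X_ab_target = binarize_atac(data.atac_counts)
    X_ab = X_ab_target if atac_input is None else np.asarray(atac_input, dtype=np.float64)
    n, d_r = X_rn.shape
    d_a = X_ab.shape[1]

    enc_r = init_encoder([d_r, cfg.hidden, cfg.d], rng, cfg.activation, "rna")
    enc_a = init_encoder([d_a, cfg.hidden, cfg.d], rng, cfg.activation, "atac")
    dec_rna = init_zinb_decoder(cfg.d, cfg.hidden, d_r, rng)
    dec_atac = init_bernoulli_decoder(cfg.d, cfg.hidden, d_a, rng)

    log.info("stage 1: pretraining autoencoders (%d epochs)", cfg.pretrain_epochs)
    _pretrain(enc_r, dec_rna, X_rn, X_r,
              lambda Z, t: zinb_nll(t, zinb_decode(Z, dec_rna)),
              cfg.pretrain_epochs, cfg.lr)
    _pretrain(enc_a, dec_atac, X_ab, X_ab_target,
              lambda Z, t: bernoulli_ce(t, bernoulli_decode(Z, dec_atac)),
              cfg.pretrain_epochs, cfg.lr)

    Z_r0 = encode(X_rn, enc_r).data
    Z_a0 = encode(X_ab, enc_a).data
    graph_r = build_adaptive_graph(Z_r0, sigma=cfg.rbf_sigma)
    graph_a = build_adaptive_graph(Z_a0, sigma=cfg.rbf_sigma)

    cent_r = init_centrality(cfg.d, rng)
    cent_a = init_centrality(cfg.d, rng)
    ms_u = init_msencoder(cfg.d, n, cfg.p, rng, alpha=cfg.alpha) if cfg.use_mscl else None
    ms_r = init_msencoder(cfg.d, n, cfg.p, rng, alpha=cfg.alpha) if cfg.use_mscl else None

    state = ModelState(config=cfg, enc_r=enc_r, enc_a=enc_a,
                       cent_r=cent_r, cent_a=cent_a, ms_u=ms_u, ms_r=ms_r,
                       dec_rna=dec_rna, dec_atac=dec_atac,
                       graph_r=graph_r, graph_a=graph_a)
    weights = LossWeights(cfg.alpha_1, cfg.alpha_2, cfg.gamma)
    opt = Adam(_collect_params(enc_r, enc_a, cent_r, cent_a, ms_u, ms_r,
                               dec_rna, dec_atac), lr=cfg.lr)

    log.info("stage 2: joint training (%d epochs)", cfg.joint_epochs)
    last_finite = None
    for epoch in range(cfg.joint_epochs):
        perm = random_derangement(n, rng) if cfg.use_mscl else None
        opt.zero_grad()
        fw = _forward(state, X_rn, X_ab, perm)
        contra = fw["contra"] if fw["contra"] is not None else 0.0
        loss = total_loss(X_r, X_ab_target, fw["zinb"], contra,
                          weights if cfg.use_mscl else
                          LossWeights(cfg.alpha_1, 0.0, cfg.gamma))
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"joint training diverged at epoch {epoch}; "
                f"last finite loss {last_finite}")
        last_finite = float(loss.data)
        js_part = float(fw["contra"].data) if fw["contra"] is not None else 0.0
        state.loss_trace.append((epoch, last_finite, js_part))
        loss.backward()
        opt.step()

    state.trained = True
    final = _forward(state, X_rn, X_ab, None)
    Z = final["Z"].data
    zp = final["zinb"]
    params = ZINBParams(Pi=zp.Pi.data, M_r=zp.M_r.data, Theta=zp.Theta.data,
                        M_a=zp.M_a.data)
    return state, Z, params


def impute(state: ModelState, data: PairedOmics) -> tuple[np.ndarray, np.ndarray]:
    """Decoder means (M_r, M_a) as the imputed RNA and ATAC matrices."""
    if not state.trained:
        raise RuntimeError("model has not been trained")
    X_rn = normalize_rna(data.rna_counts)
    X_ab = binarize_atac(data.atac_counts)
    fw = _forward(state, X_rn, X_ab, None)
    return fw["zinb"].M_r.data, fw["zinb"].M_a.data
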