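"""End-to-end orchestration: data -> training -> smoothing -> clusters.

A run is fully determined by a :class:`RunConfig` and its seed: synthesis,
parameter initialization, negative-pair sampling and K-means all draw from
it. The ablation variants mirror the component study (w/oCen: no centrality
encoding; w/oMSCL: no multi-subspace contrastive learning; w/oAdaGCN: no
adaptive graph-convolution smoothing), and the noise harness perturbs the
encoder inputs (normalized RNA / binarized ATAC) with N(0, sd^2), clipped
at zero.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import build_adaptive_graph, normalized_adjacency
from .io import (
    PairedOmics,
    binarize_atac,
    load_paired_matrices,
    normalize_rna,
    select_features,
)
from .model import ModelConfig, impute, train
from .smoothing import ClusterResult, adaptive_smooth, cluster, evaluate
from .synthetic import SyntheticSpec, add_gaussian_noise, generate_paired_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; defaults define the reference synthetic benchmark."""

    synthetic: SyntheticSpec | None = None
    rna_path: str | None = None
    atac_path: str | None = None
    format: str = "csv"
    labels_path: str | None = None
    n_top_genes: int = 2000
    n_top_peaks: int = 5000
    K: int | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    max_layers: int = 8
    use_adagcn: bool = True
    noise_sd: float = 0.0
    noise_stage: str = "normalized"   # or "counts"
    seed: int = 0

    def __post_init__(self):
        if self.synthetic is None and (self.rna_path is None or self.atac_path is None):
            self.synthetic = SyntheticSpec()
        if self.noise_stage not in ("normalized", "counts"):
            raise ValueError("noise_stage must be 'normalized' or 'counts'")

    @property
    def variant(self) -> str:
        if not self.model.use_centrality:
            return "w/oCen"
        if not self.model.use_mscl:
            return "w/oMSCL"
        if not self.use_adagcn:
            return "w/oAdaGCN"
        return "full"

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = dataclasses.replace(self)
        cfg.model = dataclasses.replace(self.model, seed=seed)
        if self.synthetic is not None:
            cfg.synthetic = dataclasses.replace(self.synthetic, seed=seed)
        cfg.seed = seed
        return cfg


def _get_data(config: RunConfig) -> tuple[PairedOmics, np.ndarray | None]:
    if config.synthetic is not None:
        data, truth = generate_paired_dataset(config.synthetic)
        return data, truth
    data = load_paired_matrices(config.rna_path, config.atac_path,
                                config.format, config.labels_path)
    truth = None
    if data.labels is not None:
        _, truth = np.unique(np.asarray(data.labels), return_inverse=True)
    return data, truth


def run_pipeline(config: RunConfig, outdir: str | None = None,
                 write_imputed: bool = False) -> ClusterResult:
    """Execute the full pipeline and optionally write artifacts to ``outdir``."""
    t0 = time.time()
    data, truth = _get_data(config)
    k = config.K or (config.synthetic.n_clusters if config.synthetic is not None
                     else None)
    if k is None:
        raise ValueError("K must be given when true labels are unavailable")

    # feature selection (no-op when the data is already at or below the cap)
    if config.n_top_genes < data.rna_counts.shape[1]:
        rna, _ = select_features(data.rna_counts, config.n_top_genes)
    else:
        rna = data.rna_counts
    if config.n_top_peaks < data.atac_counts.shape[1]:
        atac, _ = select_features(data.atac_counts, config.n_top_peaks)
    else:
        atac = data.atac_counts
    if rna is not data.rna_counts or atac is not data.atac_counts:
        data = PairedOmics(rna, atac, data.cell_ids,
                           [f"f{i}" for i in range(rna.shape[1])],
                           [f"p{i}" for i in range(atac.shape[1])],
                           labels=data.labels)

    # optional Gaussian perturbation (robustness protocol)
    rna_input = atac_input = None
    if config.noise_sd > 0:
        noise_seed = config.seed + 7919
        if config.noise_stage == "counts":
            noisy_rna = add_gaussian_noise(data.rna_counts, config.noise_sd, noise_seed)
            noisy_atac = add_gaussian_noise(data.atac_counts, config.noise_sd,
                                            noise_seed + 1)
            data = PairedOmics(noisy_rna, noisy_atac, data.cell_ids,
                               data.rna_feature_ids, data.atac_feature_ids,
                               labels=data.labels)
        else:
            rna_input = add_gaussian_noise(normalize_rna(data.rna_counts),
                                           config.noise_sd, noise_seed)
            atac_input = add_gaussian_noise(binarize_atac(data.atac_counts),
                                            config.noise_sd, noise_seed + 1)

    log.info("training (%s variant, N=%d)", config.variant, data.n_cells)
    state, Z, zinb = train(data, config.model,
                           rna_input=rna_input, atac_input=atac_input)

    trace = None
    if config.use_adagcn:
        graph_f = build_adaptive_graph(Z, sigma=config.model.rbf_sigma)
        At = normalized_adjacency(graph_f.A)
        emb, trace = adaptive_smooth(Z, At, k, config.max_layers,
                                     seed=config.seed)
    else:
        emb = Z

    labels = cluster(emb, k, seed=config.seed)
    nmi = ari = None
    if truth is not None:
        nmi, ari = evaluate(labels, truth)
        log.info("variant=%s NMI=%.4f ARI=%.4f (%.1fs)",
                 config.variant, nmi, ari, time.time() - t0)

    result = ClusterResult(labels=labels, embedding=emb, trace=trace,
                           nmi=nmi, ari=ari,
                           selected_t=(trace.selected_t if trace else None),
                           variant=config.variant)
    if outdir is not None:
        _write_artifacts(result, state, data, config, outdir, write_imputed)
    return result


def _write_artifacts(result: ClusterResult, state, data: PairedOmics,
                     config: RunConfig, outdir: str, write_imputed: bool) -> None:
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame({"cell_id": data.cell_ids, "cluster": result.labels}).to_csv(
        os.path.join(outdir, "labels.tsv"), sep="\t", index=False)
    metrics = {"variant": result.variant, "nmi": result.nmi, "ari": result.ari,
               "selected_t": result.selected_t, "seed": config.seed}
    with open(os.path.join(outdir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2)
    pd.DataFrame(state.loss_trace,
                 columns=["epoch", "total", "contrastive"]).to_csv(
        os.path.join(outdir, "loss.tsv"), sep="\t", index=False)
    if result.trace is not None:
        pd.DataFrame({"t": range(len(result.trace.xi_values)),
                      "xi": result.trace.xi_values}).to_csv(
            os.path.join(outdir, "xi_trace.tsv"), sep="\t", index=False)
    pd.DataFrame(result.embedding,
                 index=data.cell_ids).to_csv(os.path.join(outdir, "embedding.csv"))
    if write_imputed:
        m_r, m_a = impute(state, data)
        pd.DataFrame(m_r, index=data.cell_ids,
                     columns=data.rna_feature_ids).to_csv(
            os.path.join(outdir, "imputed_rna.csv"))
        pd.DataFrame(m_a, index=data.cell_ids,
                     columns=data.atac_feature_ids).to_csv(
            os.path.join(outdir, "imputed_atac.csv"))


def run_ablation(config: RunConfig, seeds: list[int]) -> pd.DataFrame:
    """Run the full model and all three single-component ablations per seed."""
    rows = []
    for seed in seeds:
        base = config.with_seed(seed)
        variants = {
            "full": base,
            "w/oCen": dataclasses.replace(
                base, model=dataclasses.replace(base.model, use_centrality=False)),
            "w/oMSCL": dataclasses.replace(
                base, model=dataclasses.replace(base.model, use_mscl=False)),
            "w/oAdaGCN": dataclasses.replace(base, use_adagcn=False),
        }
        for name, cfg in variants.items():
            res = run_pipeline(cfg)
            rows.append({"variant": name, "seed": seed,
                         "nmi": res.nmi, "ari": res.ari,
                         "selected_t": res.selected_t})
    return pd.DataFrame(rows)


def run_noise_sweep(config: RunConfig, sds: list[float],
                    seeds: list[int] | None = None) -> pd.DataFrame:
    """Clustering quality under Gaussian perturbation of the inputs."""
    if any(sd < 0 for sd in sds):
        raise ValueError("noise standard deviations must be non-negative")
    seeds = seeds if seeds is not None else [config.seed]
    rows = []
    for seed in seeds:
        for sd in sds:
            cfg = dataclasses.replace(config.with_seed(seed), noise_sd=float(sd))
            res = run_pipeline(cfg)
            rows.append({"sd": sd, "seed": seed, "nmi": res.nmi, "ari": res.ari})
    return pd.DataFrame(rows)
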