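"""Synthetic paired multi-omics data with known cluster structure.

The generator mirrors the distributional assumptions of the model itself:
RNA counts are zero-inflated negative binomial with a shared dropout
probability and cluster-specific means, ATAC peaks are Bernoulli with a
per-cluster block of "signature" peaks that are accessible more often.
A Gaussian perturbation op implements the noise-robustness protocol
(sd in {0.1, 0.3, 0.5} added to the data, clipped at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PairedOmics


@dataclass
class SyntheticSpec:
    """Parameters of the paired-omics simulation.

    ``separation`` scales the spread of per-cluster log-means: larger values
    push cluster centroids apart in expression space. ``dropout_pi`` is the
    probability of a structural (technical) zero, shared across genes to match
    the model's single zero-inflation head. Signature peaks are accessible
    with probability ``peak_on_prob`` in their own cluster and
    ``peak_off_prob`` elsewhere.
    """

    n_cells: int = 300
    n_genes: int = 150
    n_peaks: int = 200
    n_clusters: int = 3
    cluster_props: tuple = None
    rna_mean_scale: float = 8.0
    rna_dispersion: float = 2.0
    dropout_pi: float = 0.3
    peak_on_prob: float = 0.25
    peak_off_prob: float = 0.02
    separation: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.cluster_props is None:
            self.cluster_props = tuple([1.0 / self.n_clusters] * self.n_clusters)
        props = np.asarray(self.cluster_props, dtype=float)
        if len(props) != self.n_clusters:
            raise ValueError("cluster_props length must equal n_clusters")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_props must sum to 1")
        if (props < 0).any():
            raise ValueError("cluster_props must be non-negative")
        if not (0.0 <= self.dropout_pi < 1.0):
            raise ValueError("dropout_pi must lie in [0, 1)")
        if not (0.0 < self.peak_off_prob < self.peak_on_prob < 1.0):
            raise ValueError("need 0 < peak_off_prob < peak_on_prob < 1")
        if self.n_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        for name in ("n_cells", "n_genes", "n_peaks", "n_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.rna_mean_scale <= 0 or self.rna_dispersion <= 0 or self.separation <= 0:
            raise ValueError("scale, dispersion and separation must be positive")


def generate_paired_dataset(spec: SyntheticSpec, *, return_params: bool = False):
    """Sample a paired dataset; deterministic given ``spec.seed``.

    Returns ``(data, true_labels)``; with ``return_params=True`` a third
    element carries the ground-truth generative parameters (per-cell NB mean
    matrix and peak accessibility probabilities), used to score imputation.
    """
    rng = np.random.default_rng(spec.seed)
    n, g, q, k = spec.n_cells, spec.n_genes, spec.n_peaks, spec.n_clusters

    labels = rng.choice(k, size=n, p=np.asarray(spec.cluster_props, dtype=float))

    # cluster-specific NB means: shared per-gene baseline, cluster offsets
    # scaled by `separation` in log space
    base = rng.normal(0.0, 0.3, size=g)
    offsets = rng.normal(0.0, 1.0, size=(k, g)) * spec.separation
    log_mu = np.log(spec.rna_mean_scale) + base[None, :] + offsets
    mu = np.exp(np.clip(log_mu, -6.0, 8.0))  # keep counts in a realistic range

    cell_mu = mu[labels]  # n x g
    theta = spec.rna_dispersion
    # NB via gamma-Poisson mixture
    lam = rng.gamma(shape=theta, scale=cell_mu / theta)
    rna = rng.poisson(lam).astype(np.float64)
    if spec.dropout_pi > 0:
        rna[rng.random((n, g)) < spec.dropout_pi] = 0.0

    # ATAC: disjoint signature block of peaks per cluster
    block = q // k
    on_prob = np.full((k, q), spec.peak_off_prob)
    for c in range(k):
        on_prob[c, c * block : (c + 1) * block] = spec.peak_on_prob
    atac = (rng.random((n, q)) < on_prob[labels]).astype(np.float64)

    cells = [f"cell_{i:05d}" for i in range(n)]
    genes = [f"gene_{j:05d}" for j in range(g)]
    peaks = [f"peak_{j:05d}" for j in range(q)]
    data = PairedOmics(rna, atac, cells, genes, peaks,
                       labels=[int(c) for c in labels])
    if return_params:
        params = {"rna_mean": cell_mu, "peak_prob": on_prob[labels],
                  "dispersion": theta, "dropout_pi": spec.dropout_pi}
        return data, labels.astype(int), params
    return data, labels.astype(int)


def signature_blocks(spec: SyntheticSpec) -> list[np.ndarray]:
    """Peak indices of each cluster's signature block (for tests/diagnostics)."""
    block = spec.n_peaks // spec.n_clusters
    return [np.arange(c * block, (c + 1) * block) for c in range(spec.n_clusters)]


def add_gaussian_noise(matrix: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Add N(0, sd^2) noise, clipping at zero so values stay non-negative.

    ``sd = 0`` returns the input unchanged (same object semantics not
    guaranteed; values are identical).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    matrix = np.asarray(matrix, dtype=np.float64)
    if sd == 0:
        return matrix
    rng = np.random.default_rng(seed)
    noisy = matrix + rng.normal(0.0, sd, size=matrix.shape)
    return np.clip(noisy, 0.0, None)
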