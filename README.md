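# omicsfuse

Clustering of **paired single-cell multi-omics data** — scRNA-seq gene
expression and scATAC-seq chromatin accessibility measured in the *same*
cells. Single-cell counts are sparse, noisy and zero-inflated, and the two
modalities disagree in dimensionality and signal strength; naive
concatenation or single-omics clustering often fails to resolve cell types.
`omicsfuse` learns a joint embedding that preserves both what the modalities
share and what each contributes, then clusters it with an adaptively
smoothed graph convolution.

Intended users: computational biologists analysing paired multi-omics
experiments (10x Multiome-style assays), and methods researchers who want a
tested, fully deterministic reference implementation with a built-in
synthetic benchmark.

## The model

For N cells with RNA counts X^r ∈ ℝ^{N×Dr} and accessibility X^a ∈ ℝ^{N×Da}:

1. **Omics-specific autoencoders.** Encoders map the normalized RNA
   (median-library scaling + log1p) and binarized ATAC to Z^r, Z^a ∈ ℝ^{N×d}.
2. **Adaptive probability graph.** For each cell, a soft neighbor
   distribution solves the simplex-constrained program
   `min_{aᵢ≥0, aᵢᵀ1=1} Σⱼ ‖zᵢ−zⱼ‖² aᵢⱼ + ‖aᵢ−pᵢ‖²`, where P is an RBF
   guidance kernel; the closed-form solution is the Euclidean projection of
   `pᵢ − dᵢ/2` onto the probability simplex. Node degrees of the
   symmetrized graph feed a **centrality encoding**
   `ẑᵢ = zᵢ + log(1 + C·degᵢ)` (learnable C > 0), and full self-attention
   `Att = softmax(Ẑ Ẑᵀ/√d)` produces enhanced embeddings Z̃ = Att·Ẑ.
3. **Multi-subspace contrastive learning.** Each view is split into p
   subspaces by attention over learned queries with a degree-structure bias:
   `Att = softmax(K Q + α S)`, subspace k = Att[:,k]·(V B_k). Across views,
   a Jensen–Shannon lower bound on mutual information (dot-product
   discriminator, shuffled negatives) is maximized per matched subspace;
   within a view, the CLUB upper bound under N(u⁽ˡ⁾ | u⁽ᵏ⁾, β⁻¹I) is
   minimized between subspaces to enforce diversity.
4. **Fusion and generative decoding.** Z = Z^{ra} + λ_r Z̃^r + λ_a Z̃^a,
   where Z^{ra} concatenates both views' subspaces. A ZINB decoder
   (Π, M̄_r, Θ via sigmoid/exp heads) reconstructs the raw RNA counts; a
   Bernoulli decoder (M̄_a) reconstructs binary accessibility. The joint
   objective is `L = ZINB-NLL + α₁·CE + α₂·L_contrastive`, optimized with
   Adam after per-omics pretraining. The decoder means double as **imputed**
   matrices.
5. **Adaptive graph-convolution smoothing.** A fresh adaptive graph on the
   fused Z is normalized as D^{−1/2}(A_f + I)D^{−1/2} and iterated,
   X^{t+1} = Ã X^t (pure Laplacian smoothing). After every step, K-means
   labels give the intra-cluster compactness
   `ξ = (1/|C|) Σ_c |c|⁻² Σ_{i,j∈c} ‖x̂ᵢ−x̂ⱼ‖²`; the iteration stops at the
   first ξ increase, returning the depth-t embedding. Final labels are
   K-means on the smoothed embedding; NMI/ARI are reported against
   reference labels when available.

Everything differentiable runs on a small, finite-difference-verified
reverse-mode autodiff core (`omicsfuse.autodiff`) over numpy — the package
has no deep-learning framework dependency and is exactly reproducible on a
single CPU.

## Worked example

Run the full pipeline on the built-in synthetic benchmark (300 cells,
3 clusters, ZINB RNA counts with 30 % dropout, Bernoulli peaks):

```bash
$ omicsfuse run --seed 0 --out demo_run
variant=full selected_t=8 nmi=1.0 ari=1.0
```

The run recovered the three planted cell populations perfectly (NMI = 1.0,
ARI = 1.0) and selected smoothing depth t = 8. `demo_run/` contains
`labels.tsv` (cell → cluster), `metrics.json`, the per-epoch loss trace,
the ξ trace (here ξ fell 68.87 → 37.74 → 23.28 → … over the first steps,
so smoothing kept contracting the clusters), and the embedding coordinates.

The same pipeline runs on your own data:

```bash
omicsfuse run --config my_run.yaml --out results/
```

with a YAML config pointing at CSV/TSV matrices (cells × features, first
column = cell barcode) or MatrixMarket triplets with `barcodes.tsv` /
`features.tsv` companions, plus an optional labels file. Ablation variants
(`--no-centrality`, `--no-mscl`, `--no-adagcn`), the synthetic generator
(`omicsfuse synth`), an ablation table (`omicsfuse ablate`) and a
Gaussian-noise robustness sweep (`omicsfuse noise-sweep`) are also exposed.
From Python, `omicsfuse.run_pipeline(RunConfig(...))` returns labels,
embedding, smoothing trace and scores.

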