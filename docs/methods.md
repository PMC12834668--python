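# Methods

## Model and assumptions

`omicsfuse` treats a paired experiment as N cells observed under two noise
models: RNA counts are zero-inflated negative binomial (ZINB) — a point mass
at zero with probability π (technical dropout) mixed with NB(μ, θ) — and
peak accessibility is Bernoulli after binarization. The NB probability mass
function is evaluated with its 1/x! normalizer (via log-gamma), so the
likelihood is proper and the x = 0 mixture is computed by log-sum-exp of the
two branches. Encoders see the normalized data (median-library scaling +
log1p for RNA; presence/absence for ATAC), while likelihoods are always
evaluated against the observed raw counts / binary matrix: normalization is
a representation choice, not a change of the data the model explains.

Median-target normalization is deliberately *not* scale-free: scaling all
counts by c scales the pre-log matrix by exactly c
(`normalize(cX) = log1p(c · expm1(normalize(X)))`), because the target is
the data's own median library. The per-cell scale factors are what is
invariant. This is the behavior asserted in the tests.

The method assumes the two modalities index the same cells in the same
order; barcode mismatches are an error, never an implicit intersection.

## Graph construction

Per cell the soft neighbor distribution solves
min_{a≥0, aᵀ1=1} Σⱼ d²ᵢⱼ aᵢⱼ + ‖aᵢ − pᵢ‖², whose solution is the simplex
projection (sort-based, O(N log N) per row) of pᵢ − d²ᵢ/2, with the
self-term excluded and the diagonal forced to zero.

Two numerical decisions matter here:

* **Bandwidth standardization.** The guidance pᵢ is unitless (RBF kernel
  values in [0,1]) while d² carries squared embedding units. Solved on raw
  coordinates the distance term dominates and every row collapses onto its
  single nearest neighbor — a hard 0/1 graph, which defeats the purpose of
  a soft probability graph. The pipeline therefore solves the row problem
  in bandwidth-standardized coordinates Z/σ, with σ the same
  median-heuristic bandwidth the RBF kernel uses, making the two objective
  terms commensurate. On the reference benchmark this yields ~20–25
  soft neighbors per row at ~97 % within-cluster mass, versus ~1.3
  neighbors unstandardized. The row solver itself (`solve_adaptive_graph`)
  is agnostic: it solves whatever (Z, P) it is given and is verified
  against a general constrained-QP oracle.
* **Degrees on the symmetrized graph.** Row sums of a row-stochastic matrix
  are identically 1 and carry no signal, so centrality uses
  deg = ((A + Aᵀ)/2)·1: cells chosen as neighbors by many others exceed 1.
  Total degree mass is conserved (Σ deg = N).

The smoothing adjacency is the standard symmetric normalization
D^{−1/2}(A_sym + I)D^{−1/2}; its spectral radius is 1, which is what makes
repeated propagation a contraction (Laplacian smoothing) rather than an
amplifier.

## Centrality, attention, subspaces

The centrality vector is reparameterized as C = softplus(c_raw) so
log(1 + C·deg) is defined and monotone for all deg ≥ 0, and is exactly zero
at degree 0. Self-attention is full N×N (no graph masking) with the 1/√d
temperature. The multi-subspace encoder shares one value embedding
V = Z W_V across p subspaces, scales it by the subspace-attention weight
softmax(K Q + α·diag(deg) W_S), and projects each subspace with its own
matrix B_k to d_sub = d/(2p) dimensions, so the two flattened views
concatenate to exactly width d. With d = 60 and p = 3 (the default subspace
count), d_sub = 10. The default embedding width is 60 rather than a
round 64 precisely so that it is divisible by 2p for p = 3. W_S has one row
per cell, which makes it dataset-size-bound; it is initialized per run.

## Mutual-information estimators

Cross-view agreement uses the Jensen–Shannon lower bound with a dot-product
discriminator; negatives are a fresh seeded derangement of the batch each
epoch (a sample from the product of marginals with no fixed points). The
estimator is ≤ 0 by construction and −2 log 2 at zero embeddings.
Within-view redundancy uses the CLUB upper bound with the fixed Gaussian
conditional N(u⁽ˡ⁾ | u⁽ᵏ⁾, β⁻¹I); the Gaussian constants cancel, leaving
(β/2)·(E_{i≠j}‖u⁽ˡ⁾ⱼ − u⁽ᵏ⁾ᵢ‖² − E_i‖u⁽ˡ⁾ᵢ − u⁽ᵏ⁾ᵢ‖²).

Both estimators scale with the *square of the embedding norm*: the CLUB
penalty in particular can be driven to −∞ simply by inflating magnitudes,
which destabilizes joint training (we observed exactly this: one subspace
ballooning while attention saturates). During training the MI terms are
therefore evaluated on L2-row-normalized subspace embeddings. The public
estimator functions remain unnormalized — they compute exactly the
quantities defined above on whatever inputs they receive.

## Training

Two stages, all full-batch Adam (lr 1e-3):

1. **Pretraining** (default 60 epochs): each autoencoder on its own
   likelihood (ZINB for RNA, cross-entropy for ATAC).
2. **Joint** (default 150 epochs): the total objective
   L = ZINB-NLL + α₁·CE + α₂·(−Σₖ JS + γ Σ_{k<l} CLUB) over encoders,
   centrality, attention, subspace encoders and decoders. The adaptive
   graphs (and hence degrees) are built once from the pretrained
   embeddings; re-solving the O(N²) QP every epoch buys nothing measurable
   at these sizes.

Defaults: λ_r = λ_a = 0.1, α₁ = 0.1 (cross-entropy is large per entry and
needs the smaller weight), α₂ = 1.0, γ = 1.0, β = 1.0, ELU activations,
256-unit hidden layers. The schedule lengths were chosen where the joint
loss plateaus on the reference problem sizes (extending to 400 epochs
changes ARI by < 0.01); they are config fields, not constants.

Stability guards: exp heads are clamped to [1e-5, 1e6] and sigmoid heads to
[1e-7, 1 − 1e-7] (float64 sigmoid saturates exactly beyond |logit| ≈ 37,
which would put 0/1 outside the Bernoulli/ZINB domains); gradients pass
only inside the clamp. Divergence (non-finite loss) aborts with the last
finite epoch reported rather than continuing silently.

Ablation variants: w/oCen skips the centrality addition (Ẑ = Z); w/oMSCL
replaces Z^{ra} with the plain concatenation of the first d/2 columns of
Z^r and Z^a and drops the contrastive term; w/oAdaGCN clusters the fused Z
directly.

## Adaptive smoothing depth

After fusion, X^{t+1} = Ã X^t is iterated (parameter-free Laplacian
smoothing; a weighted ReLU(Ã X W) propagation step and an MSE loss are
provided as building blocks, but the depth-selection rule below is the
actual mechanism and the only mode the pipeline uses). After each
step, K-means (n_init = 20, fixed seed) labels the current embedding and
ξ = mean over clusters of the ordered-pair average squared distance is
recorded; the first strict increase ξ^(t+1) > ξ^(t) stops the iteration at
depth t. Ties continue. The cap is max_layers = 8 by default. Because ξ is
an absolute quantity and propagation is a contraction, ξ often decreases
monotonically on well-separated data and the cap binds; the early stop
fires reliably when the graph disagrees with the feature clusters (e.g. a
chain graph over interleaved clusters, which is the over-smoothing-prone
case in the tests).

## Synthetic benchmark: what it shows and what it cannot

The generator plants K clusters with log-normal cluster/gene means
(spread scaled by `separation`), samples RNA as gamma–Poisson (NB) with a
shared dispersion θ_sim and applies structural dropout with probability
π ∈ [0,1); ATAC gives each cluster a disjoint signature block of peaks
(on-probability 0.25 vs 0.02 background). Reference conditions: N = 300,
150 genes, 200 peaks, K = 3, θ_sim = 2, dropout 0.3, separation 1.5
("high") or 0.4 ("moderate"). The noise protocol perturbs the *encoder
inputs* (normalized RNA, binarized ATAC) with N(0, sd²) clipped at 0 for
sd ∈ {0.1, 0.3, 0.5}; likelihood targets stay the observed data, since the
Bernoulli domain requires exact {0,1}. A pre-normalization variant
(`noise_stage="counts"`) exists but note that clip-then-binarize turns
roughly half the zero entries positive at any sd, which makes the
perturbation nearly sd-independent for ATAC — the post-normalization stage
is the meaningful one and the default.

The generator emulates the *same likelihood family the decoders assume*.
That is a feature for testing (parameter recovery is well-posed; the
reference benchmark is recovered at ARI = NMI = 1.0) and a limitation for
module comparison: when the data exactly matches the ZINB/Bernoulli model,
reconstruction alone is near-optimal, and the contrastive term — which
trades reconstruction fidelity for cross-view alignment and subspace
diversity — can only cost. The ablation table computed by the test suite
shows precisely this: centrality and adaptive smoothing do not hurt and
modestly help at moderate separation, while the w/oMSCL variant (pure
reconstruction) matches or exceeds the full model there. This is a
statement about ZINB-faithful synthetic data at N = 300, not about real
multi-omics data, where representations must cope with structure no ZINB
fit explains. Features of real data the generator does not emulate: batch
effects, library-size gradients, per-gene dropout rates, peak
co-accessibility, doublets, trajectories.

Problem sizes throughout (N = 300, 5 seeds for direction checks, 3 for
recovery) are the package's reference configuration; the method is dense
O(N²) in the graph and attention stages, and a config warning triggers
above 50k cells.

## Known limitations

* Dense N×N graphs and attention; no approximate-NN backend.
* Full-batch training only at reference scale; mini-batching would
  invalidate the N×N attention without within-batch recomputation.
* W_S (degree bias of the subspace attention) is per-cell and cannot be
  transferred across datasets of different size.
* The ξ stopping rule rarely fires on cluster-consistent graphs (the
  max_layers cap binds instead); its value shows on graph/feature
  disagreement.
* Θ is modeled per entry (matrix output of the dispersion head); a
  per-gene dispersion variant is a natural extension but is not
  implemented.
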