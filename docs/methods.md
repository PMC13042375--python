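# Methods

## Overview

stVGP models a stack of serial 2D spatial-transcriptomics sections with a
variational autoencoder whose latent prior is a nearest-neighbor Gaussian
process over the spot coordinates. Three capabilities follow from that one
latent model: (i) spatial-domain detection with batch correction across
slices, (ii) hybrid rigid/non-rigid registration of the slices into one 3D
frame, and (iii) "virtual slices" — decoding the GP predictive posterior at
unsampled 3D locations, including cross-modal decoding of expression from
histology-image embeddings.

## Spatially variable gene selection

Each slice is cut into an `n_intervals x n_intervals` grid of equal-width
cells over its bounding box (default 4 per axis; cells with fewer than 10
spots are skipped). Within each cell, Moran's I is computed per gene,

I = (m / ΣW) · Σ_ab w_ab (x_a − x̄)(x_b − x̄) / Σ_a (x_a − x̄)²,

with binary k-nearest-neighbor weights (k = 6, max-symmetrized) — the
hexagonal Visium neighborhood. Genes are ranked by the **variance** of their
I values across all cells and slices: a gene that is strongly
autocorrelated in some regions and flat in others is spatially informative,
while both globally smooth backgrounds and pure noise have low I variance.
An optional prefilter (on by default) keeps, per cell, only genes
differentially expressed versus the rest of the slice (two-sided Wilcoxon
rank-sum, Benjamini–Hochberg FDR < 0.05). Genes with fewer than 3 defined I
values are excluded; NaN (constant) cells are ignored.

## Latent model

Per spot n the encoder (2 hidden layers, default 512/128, ELU, layer-norm)
produces a diagonal Gaussian posterior q(h_n) = N(μ_φ(x_n), σ²_φ(x_n) I_L)
with L = 16 by default. The prior ties each spot to its K = 6 nearest
within-slice neighbors through the RBF-kernel GP predictive conditional

p(h_j | h_nei(j), Θ) = N( m_j + μ_Θ , v_j I ),
m_j = K_jn (K_nn + εI)⁻¹ H_nei(j),  v_j = k_jj − K_jn (K_nn + εI)⁻¹ K_nj,

where μ_Θ is a trainable per-slice (batch) latent mean. The ELBO per slice
is a single-sample Gaussian reconstruction term (per-gene learned noise
variance) minus the closed-form KL between the diagonal posterior and this
conditional prior, with neighbor latents plugged in at their posterior
means (mean-field plug-in; chosen over a sampled KL for variance reduction
at full-batch scale). With K = 0 and μ_Θ = 0 the objective reduces exactly
to a plain VAE with a standard-normal prior — this limit is enforced by an
oracle test against an independently coded VAE ELBO.

Kernel hyperparameters are fixed at initialization (lengthscale = median
nearest-neighbor spot distance, unit variance) rather than trained:
differentiating through the per-spot K×K solves buys nothing measurable at
these problem sizes and keeps the KL closed-form and cheap. Jitter is
1e-5 × variance, doubled up to 3 times on factorization failure, and acts
as a nugget: the factorized prior density equals the dense
multivariate-normal density under K + jitter·I exactly (oracle-tested).

### Batch correction

The learned batch mean μ_Θ absorbs the first-order (mean) component of
slice-level technical variation; the batch-corrected latent is
μ_φ(x) − μ_Θ[batch]. Mean subtraction alone is insufficient: a logistic
classifier still identifies the slice from the corrected latent at 0.8–0.95
accuracy on synthetic data, because the encoder transmits higher-order
batch signatures. We therefore add a pairwise maximum-mean-discrepancy
penalty between the corrected latent clouds of every slice pair (multiscale
Gaussian kernels at {0.5, 1, 2} × median pairwise distance), weight
`lambda_batch` = 1e4 on the summed-ELBO scale. This drives the classifier
to chance while leaving domain recovery intact; it reuses the same MMD
device the model applies across modalities.

### Cross-modal coupling

With image embeddings present, a second encoder/decoder pair learns H²
under the same GP prior, and three terms couple the modalities: global MMD
between H¹ and H², the mean per-spatial-neighborhood MMD (local
consistency), and a pointwise contrastive ratio ‖H¹−H²‖²_F / ‖H¹+H²‖_F
(ε-guarded denominator). Their common weight λ₁ defaults to 10: because
the ELBO terms are sums over spots and genes, small weights leave the
latent clouds unaligned and the expression decoder cannot decode image
latents (cross-modal marker correlation ≈ 0.15 at λ₁ ≤ 1, ≈ 0.81 at λ₁ =
10, plateauing by λ₁ = 100). Prediction from images alone encodes the
embeddings with the image encoder and decodes the posterior mean with the
*expression* decoder.

### Optimization

Adam at lr 3e-3 for 400 epochs (defaults), full batch, all randomness from
one seed; training is bit-reproducible on CPU. A lower lr of 1e-3
demonstrably underfits at full-batch desk scale (marker reconstruction
r ≈ 0.6 vs ≈ 0.98). Clustering of the corrected latent uses Leiden on a
15-NN graph or k-means with fixed k.

## Hybrid alignment

**Rigid stage.** For the top-m (default 30) spatially variable genes, each
slice contributes one landmark: the expression-weighted centroid
Σ_n z_n x_{n,g} / Σ_n x_{n,g}. A closed-form Procrustes similarity
transform seeds the mapping; a small tanh MLP (2×64, zero-initialized
output) refines the residual on the landmarks. Training stops early when
the seed already fits (Adam otherwise converts vanishing gradients into
lr-sized drift). Collinear landmarks fall back to an identity seed.

**Non-rigid stage.** A 3-layer single-head attention spatial transformer
acts on the raw moving coordinates: per layer, 2×2 query/key/value
projections, scores (QᵀK)/2 clipped to ±5, plus a log-domain k-NN mask with
a strictly decreasing neighbor schedule (32, 16, 8), then a residual
feed-forward block (hidden 32) on layer-normed coordinates. Zero-initialized
value and output projections make the STN the exact identity at
initialization; the map is permutation-equivariant.

**Fusion and objective.** Per spot, a shared scorer softmax
(W_attᵀ tanh(W z + b)) produces weights α over the rigid and non-rigid
candidates; Ẑ = α₁ Z_rigid + α₂ Z_nonrigid. The STN and fusion parameters
minimize ‖Ẑ − Z_target‖²_F, where each moving spot's target is the
coordinate of its nearest template spot **in latent space** — trained-model
latents when available, otherwise a 20-component PCA of the shared
normalized expression (coordinate-space matching collapses under large
rotations; expression-based matching does not). Stacks are aligned by
chaining: slice i registers onto the already-aligned slice i−1; z positions
(cumulative section spacings) become the third coordinate.

The attainable same-label nearest-neighbor distance after perfect alignment
is bounded below by the spot spacing and warp residual; for small rotations
the unaligned distance is already near that floor, so relative-improvement
summaries are only informative when rotations are substantial.

## Virtual slices

The latent posterior at a 3D query is the GP conditional over its K = 10
nearest aligned spots with neighbor posterior means plugged in. The 3D
kernel lengthscale is the median distance to the nearest spot on a
*different* z-plane — using the (much finer) in-plane spacing would zero
out cross-plane weights and shrink every interpolation to the prior.
Expression is the average of decoded latent samples (default 30 Monte-Carlo
draws), i.e. sampling precedes decoding. Leave-one-slice-out evaluation
retrains from scratch without the masked slice (no leakage through
optimizer state; bit-identity under zeroing of the masked expression is
tested) and predicts at the masked slice's own coordinates.

## Synthetic benchmark

The generator emulates serial Visium sections of layered tissue: jittered
hexagonal spot lattice; 4 horizontal-band domains shared across slices with
a small per-slice boundary wobble; 15 marker genes per domain at +1.2
log-fold over a per-gene baseline; a weak smooth low-rank spatial
background (sd 0.1 per component) shared across slices; per-slice per-gene
additive batch shifts (sd 0.3) in log space; spot-level Gaussian noise (sd
0.3); per-slice rotations (30° increments by default), optional
translations and sinusoidal warps; and image embeddings mixing a linear map
of domain one-hots and the smooth field with isotropic noise at a
configurable signal fraction (default 0.8, dimension 64). An optional
negative-binomial count mode exercises the normalization path. Defaults
were chosen to reflect layered cortex-like data, where domain programs —
not smooth gradients — dominate spatial expression variance.

What the generator does **not** emulate: empirical Visium count-depth and
dropout distributions, segmentation errors, partial tissue overlap between
sections, or real histology texture (embeddings are a linear surrogate for
CNN features). Passing tests therefore demonstrate correct mechanism and
recovery under controlled conditions, not performance claims on real data.

## Problem sizes and numerical choices

Tests and the acceptance script run stacks of 2–4 slices × 250–300 spots ×
100–200 genes with 200–300 training epochs and the 50 top spatially
variable genes — sizes at which every stage's behavior (recovery, mixing,
determinism) is already expressed. Degenerate inputs: all-zero spots pass
through normalization unchanged with a warning; constant genes give NaN
Moran's I and rank last; K ≥ N neighbor requests clamp to N−1; nearest-
neighbor ties break to the lowest index everywhere; the contrastive
denominator is ε-guarded; GP conditional variances are clamped at zero.

## Known limitations

- The cross-modal path assumes embeddings that are (noisily) linear in
  domain identity; real CNN features are not, and the coupling weight λ₁
  may need re-calibration per dataset.
- Chained pairwise alignment accumulates drift over long stacks; no joint
  multi-slice objective is optimized.
- The rigid stage depends on landmark correspondence, which degrades when
  slices do not share their spatially variable genes (e.g., strongly
  non-adjacent sections).
- Batch correction targets additive slice-level effects; depth- or
  cell-composition-driven technical variation is out of scope.
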