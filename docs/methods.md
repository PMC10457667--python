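# Methods

## Problem setting and assumptions

`nclabel` transfers cell-type labels from a labeled scRNA-seq reference
(gene expression matrix, GEM) to an unlabeled scATAC-seq target represented
as a gene activity matrix (GAM) over the same gene vocabulary. This is a
semi-supervised, open-set problem: the target may contain types absent from
the reference. Three assumptions underpin the model:

1. **Shared gene space.** After GAM conversion, a gene's activity in the
   target is (noisily, monotonically) related to its expression in the
   reference, so a shared encoder can place both modalities in one latent
   space. Gene matching is exact string match after whitespace trimming —
   no ortholog or alias resolution.
2. **Lossy conversion.** The GAM loses information relative to the raw
   peak/bin features: cells that are near (far) in raw accessibility space
   may be far (near) in gene-activity space. The contrastive term assumes
   the user can supply a low-dimensional representation of the raw features
   (PCA or tSNE coordinates) in which nearest neighbors are meaningful.
3. **Novelty shows as low confidence.** Types never seen by the classifier
   should receive diffuse softmax probabilities. This requires the encoder
   not to collapse novel-type cells onto reference clusters — the reason the
   alignment loss only acts on the best-matched top-p fraction and the
   contrastive loss keeps raw-space neighborhoods coherent.

## Objective

With reference batch B_l (size N, labels y) and target batch B_u (size N),
embeddings h = f(x) and probabilities r = softmax(g(h)):

    L = L_CE + 0.1 L_PR + λ₁ L_FA + λ₂ L_NCL

* **L_CE** = −(1/N) Σ_b log r_b(y_b), computed from logits via a stable
  log-softmax.
* **L_NNDR(B)** = (1/(N·d) Σ_b Σ_j |h_b(j) − h̄(j)|)⁻¹
  + (1/d²) Σ_{i≠j} |A_ij| + (1/d) Σ_j |h̄(j)|, where A is the Pearson
  correlation matrix of the batch (zero-variance dimensions get correlation
  0) and h̄ the batch mean. **L_PR** = L_NNDR(B_u) + L_NNDR−(B_l), the
  reduced form dropping the inverse-variability term on the labeled side,
  whose variance is already driven up by L_CE; keeping it symmetric would
  let the modalities' scales drift apart.
* **L_FA**: for each target cell b, i(b) = argmax_i cos(h_b, h_i) over the
  reference batch (ties → lowest index); F_p = the ⌈p·N⌉ target cells with
  the highest best-match similarity (ties → lowest index);
  L_FA = −(1/|F_p|) Σ_{b∈F_p} cos(h_b, h_{i(b)}). |F_p| = ⌈p·N⌉ is never 0.
* **L_NCL**: with σ(a,b) = exp(⟨a,b⟩/(τ‖a‖‖b‖)) and ĥ_b the embedding of a
  neighbor sampled uniformly from b's k₀-NN set,
  L_NCL = −(1/2N) Σ_b [log σ(h_b,ĥ_b)/D1_b + log σ(ĥ_b,h_b)/D2_b], where
  D1_b sums σ(h_b,·) over all partners and all other anchors, and D2_b
  symmetrically. Each numerator appears in its own denominator, so
  L_NCL ≥ 0; it is exactly 0 at N = 1.

Gradient routing: L_CE reaches encoder and classifier; the three
regularizers consume embeddings only, so their gradients stop at the
encoder automatically. Gradients flow through both arguments of every
cosine (no stop-gradient). Embeddings are not L2-normalized before the
classifier; σ normalizes internally.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| d (embed_dim) | 64 | latent dimensionality; ≥ 2 required by the correlation term |
| encoder_hidden | [256] | one rectified hidden layer. A purely linear encoder keeps novel clusters linearly separable from everything, which lets the linear classifier assign them *confident* wrong labels; one hidden layer lets the encoder place unseen types off the class simplex, which is what makes ẽ informative |
| k₀ | 15 | neighborhood size of the raw-feature kNN graph; conventional single-cell choice, graph built once before training |
| τ | 0.2 | contrastive temperature. Smaller values sharpen the contrast but over-fragment clusters at desk-scale batch sizes; 0.2 balanced structure preservation and open-set separation during calibration on the synthetic benchmark |
| p (top_p) | 0.8 | fraction of best-matched target cells entering L_FA; must stay below 1 when the target contains unmatched (novel) cells |
| λ₁, λ₂ | 1.0, 1.0 | weights of alignment and contrastive terms |
| PR weight | 0.1 | fixed coefficient of L_PR in the objective (configurable override) |
| batch_size | 256 | per modality; ≥ 2 required by the regularizers |
| epochs | 150 | an epoch is one pass over the larger modality (~4 batches at the default benchmark size), the smaller modality cycling through reshuffled permutations; 150 epochs ≈ 600 steps, which the loss traces show is past convergence |
| optimizer | adam (lr 1e-3) | default; SGD with momentum 0.9 available (`optimizer: sgd`) |
| normalize | log1p CPM, scale 1e4 | per-cell library-size normalization applied identically to both modalities (switchable off); standard practice, keeps the shared space comparable |

All randomness — initialization (Glorot-uniform), shuffling, neighbor
sampling — derives from one run seed.

## Numerical choices

* Degenerate batches: the inverse mean-absolute-deviation term is guarded
  as 1/(MAD + 1e-8) with a warning when MAD ≈ 0, avoiding infinities at
  the first steps.
* Zero-norm embeddings: cosine treated as 0 with a warning in L_FA (dead
  units early in training are tolerable); hard error in L_NCL, whose
  exponentials require norms.
* Ties: argmax ties (best match, predicted class) and top-p cut ties break
  to the lowest index; kNN distance ties break to the ascending cell index.
  All outputs are deterministic given a seed.
* AUROC uses the Mann–Whitney formulation (ties count ½), computed from
  ranks. OSCR uses the discrete convention Σ_novel CCR(e_j)/n_novel with
  strict inequality e > θ; when every novel confidence lies below every
  common confidence this equals the zero-threshold accuracy. Both are
  validated against brute-force oracles; other published OSCR conventions
  may differ in the third decimal on small sets.
* Non-finite loss components abort training with a message naming the
  component.

## The synthetic benchmark

`simulate.make_benchmark` draws each cell type as a Gaussian cluster in a
10-d latent space (orthonormal mean directions, separation 6). Within-type
variation is *anisotropic*: a geometrically decaying spectrum (amplitude 2,
ratio 0.35) with a random orientation per type shared by both modalities —
emulating the low-dimensional continuous heterogeneity (activation states,
gradients) inside real cell types. The reference renders
softplus(latent · W) plus truncated Gaussian noise and a lognormal library
factor; only common types appear, with labels. The target renders 2000
peak-like binary raw features (10 per gene, loadings jittered around the
gene's loading, binarized at staggered per-feature quantile thresholds — a
graded "thermometer" code, like peaks of a locus opening progressively),
takes the top-50 principal components as the low-dimensional representation,
and aggregates each gene's features into the GAM. A `distortion` parameter
mixes that faithful aggregation with a rank-2 scramble: at 0 the GAM
preserves raw-space 10-NN neighborhoods (overlap > 0.9), near 1 it destroys
them; dropout then zeroes entries at random. Truth labels (including a
target-only novel type) are returned separately.

What it does **not** emulate: real peak structure and genomic coordinates,
batch effects, doublets, ambient contamination, imbalanced type frequencies,
or any nonmonotone expression–accessibility relationship. Passing tests
therefore show the machinery is correct and the method behaves as designed
under its own assumptions — not that any particular accuracy will transfer
to a given atlas.

Default study conditions: 3 common + 1 novel type, 200 reference and 300
target cells per type, M = 200 genes, 2000 raw features, distortion 0.3,
dropout 0.1. The heavier-distortion setting (0.7) is used to demonstrate
the contrastive term's effect: without it (λ₂ = 0) transfer accuracy
collapses toward chance while raw-neighborhood preservation in the
embedding drops several-fold.

## Design choices that were genuinely open

* **Correlation, not covariance**, in the orthogonality term: scale-free,
  and covariance would double-penalize the variance the first term rewards.
* **Euclidean metric** on the supplied low-dimensional coordinates for the
  kNN graph; the graph is directed and static (built once).
* **Neighbor sampling with replacement** across steps, uniform within each
  neighbor set — a fresh draw every step.
* **Epoch convention** over the larger modality (usually the target), the
  smaller stream cycling; trailing partial batches dropped so every step
  sees equal-sized two-stream batches.
* **Training backend**: a compact built-in reverse-mode autodiff over numpy
  (the models are two or three affine maps — a heavyweight framework would
  dominate install cost without changing results). Analytic gradients are
  verified against central finite differences in the test suite.
* **Label vocabulary from the reference only**, lexicographically ordered;
  evaluation treats any truth label outside it as novel ground truth.

## Known limitations

* Exact kNN search is O(n²) per block; fine to ~10⁵ cells, not for
  million-cell atlases (an approximate index would slot in behind
  `build_knn_graph`).
* Confidence is the raw maximum softmax probability — no temperature
  scaling or other post-hoc calibration; the `call_novel` threshold
  (default 0.5) is a convention, and the threshold-free AUROC/OSCR are the
  more trustworthy summaries.
* Single-threaded CPU implementation; no GPU path.
* The evaluation suite assumes one flat label set; hierarchical or fuzzy
  type relationships are not modeled.
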