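# nclabel

Cross-modal cell-type **label transfer from scRNA-seq to scATAC-seq** with
neighborhood-contrastive regularization, including confidence-based detection
of cell types that are absent from the reference ("novel" types).

## Who this is for

Annotating scATAC-seq cells is hard: the peak/bin feature space is huge,
extremely sparse, and not shared with scRNA-seq. A common workaround converts
accessibility into a **gene activity matrix (GAM)** so both modalities live in
the same gene space — but that conversion loses information and distorts
cell–cell distances. `nclabel` is for anyone who has

1. a **labeled reference**: a cells × genes expression matrix (GEM) from
   scRNA-seq with per-cell type labels,
2. an **unlabeled target**: a cells × genes GAM derived from scATAC-seq
   sharing the reference's gene vocabulary, and
3. a **low-dimensional representation of the target's raw accessibility
   features** (e.g. principal-component or tSNE coordinates of the peak
   matrix),

and wants per-cell type predictions with calibrated confidences, plus
open-set metrics when ground truth is available. Peak calling and GAM
construction themselves (Signac/ArchR territory) are out of scope — the tool
consumes a precomputed GAM.

## The model

A shared encoder f maps both modalities' gene-space profiles to embeddings
h ∈ R^d; a classifier g maps embeddings to K-class softmax probabilities
r. The predicted type is ŷ = argmax_k r(k), its confidence e = max_k r(k),
and the novel-type confidence is ẽ = 1 − e; cells with e below a threshold
are flagged as a possible novel type. Training minimizes

    L = L_CE + 0.1 · L_PR + λ₁ · L_FA + λ₂ · L_NCL

- **L_CE** — cross-entropy on the labeled reference batch (supervises both
  encoder and classifier).
- **L_PR** (projection regularization) — an asymmetric pairing of the NNDR
  regularizer: on the target batch the full form (inverse mean absolute
  deviation + mean off-diagonal |correlation| + mean |dimension mean|),
  which pushes toward high-variance, decorrelated, zero-mean embedding
  dimensions; on the reference batch the variance term is dropped, since
  cross-entropy already grows that side's variance.
- **L_FA** (feature alignment) — for each target cell, find the reference
  cell with the highest cosine similarity in embedding space; average the
  negative cosine over the top-p fraction of best-matched target cells.
  Well-matched cells are pulled across modalities; poorly matched cells
  (candidate novel types) are left alone.
- **L_NCL** (neighborhood-contrastive) — before training, a k₀-nearest-
  neighbor graph is built on the *raw-feature* coordinates. Each step, every
  target cell is paired with one sampled neighbor and a two-sided
  temperature-scaled contrastive loss (cosine/τ inside the exponential)
  pulls the pair together and pushes the rest of the batch apart. This
  preserves raw-space neighborhood structure that the GAM conversion
  destroyed — the core idea of the method.

All four losses, their gradients (via a small built-in reverse-mode
autodiff), the exact-kNN graph, the two-stream minibatch sampler, and the
evaluation statistics (common-type accuracy, per-type F1, novel-type AUROC,
OSCR) are implemented here and tested against independent naive oracles.

## Worked example

A built-in generator simulates linked two-modality benchmarks: shared latent
cell populations, a labeled GEM, and a target whose gene-level view is an
information-lossy transform (`distortion`) of a binary raw feature space.
The default has 3 common types + 1 target-only novel type, 600 reference and
1200 target cells.

```python
from nclabel import (CrossModalLabelTransfer, SyntheticConfig, TrainConfig,
                     make_benchmark, call_novel)

bench = make_benchmark(SyntheticConfig(seed=1))
model = CrossModalLabelTransfer(bench["reference"], bench["target"], bench["rep"],
                                train_config=TrainConfig(seed=1))
results = model.fit()
print(results.summary())

prediction = results.predict()
flags = call_novel(prediction, threshold=0.5)
report = results.evaluate(bench["truth_labels"])
print(f"common-type accuracy: {report.common_accuracy:.3f}")
print(f"novel-type AUROC:     {report.novel_auroc:.3f}")
print(f"OSCR:                 {report.oscr:.3f}")
```

Output (abridged; ~10 s on one CPU):

```
Cross-modal label transfer — fit summary
================================================
genes (M):            200
embedding dim (d):    64
classes (K):          3
encoder hidden:       [256]
optimizer:            adam (lr=0.001)
epochs x batches:     150 x 4
neighborhood size k0: 15
loss weights:         pr=0.1 lambda1=1.0 lambda2=1.0 tau=0.2 p=0.8
------------------------------------------------
first-epoch loss:     6.7680
final-epoch loss:     3.5620
final CE/PR/FA/NCL:   0.0001 / 1.6463 / -0.9296 / 4.3269
classes:              type_0, type_1, type_2

common-type accuracy: 0.994
novel-type AUROC:     0.929
OSCR:                 0.928
```

Reading the numbers: 99.4% of the 900 target cells whose true type exists in
the reference are labeled correctly. AUROC 0.929 means a randomly chosen
novel-type cell outranks a randomly chosen common-type cell by novel
confidence ẽ 93% of the time; OSCR summarizes the trade-off between correct
classification and novel-type rejection as the confidence threshold sweeps.
The rank-based metrics are threshold-free — a hard `call_novel` threshold of
0.5 is conservative here (it flags only the lowest-confidence cells), so
choose it per application, e.g. from the confidence histogram
(`nclabel.confidence_histogram`).

## Command line

The same pipeline as four subcommands with a strict YAML config
(`--seed` overrides the config's seed; every run writes its resolved
configuration next to its outputs):

```bash
nclabel simulate --config cfg.yaml --outdir data/
nclabel train    --config cfg.yaml --outdir run/
nclabel predict  --checkpoint run/checkpoint.npz \
                 --target-mtx data/target.mtx \
                 --target-cells data/target.cells.txt \
                 --target-genes data/target.genes.txt \
                 --out preds.tsv
nclabel evaluate --predictions preds.tsv --truth data/truth_labels.tsv \
                 --out report.json
```

Accepted matrix formats: Matrix Market + cell/gene sidecars, dense CSV/TSV,
and `.h5ad` through the library API.

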