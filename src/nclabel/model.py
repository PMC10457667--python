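"""Model objects: a shared encoder + classifier trained with four losses.

The public surface follows the fit/results convention: construct a
:class:`CrossModalLabelTransfer` from a labeled reference expression
dataset, an unlabeled target gene-activity dataset, and low-dimensional
coordinates of the target's raw features; call :meth:`fit` to train; the
returned :class:`LabelTransferResults` carries the learned parameters,
the per-step loss history, and prediction / evaluation methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .io import (
    ExpressionDataset,
    LabelVocabulary,
    LowDimRep,
    align_genes,
    encode_labels,
    normalize_log_cpm,
)
from .losses import (
    LossWeights,
    ce_loss_from_logits,
    fa_loss,
    ncl_loss,
    pr_loss,
    total_loss,
)
from .neighbors import KnnGraph, build_knn_graph, sample_positive_partners

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "CrossModalLabelTransfer",
    "LabelTransferResults",
    "epoch_minibatches",
]


@dataclass
class ModelConfig:
    """Encoder/classifier architecture.

    The encoder maps the M-dimensional gene space to a d-dimensional
    embedding, optionally through hidden rectified layers; the classifier is
    a single affine map from the embedding to K class logits.
    """

    input_dim: int
    n_classes: int
    embed_dim: int = 64
    encoder_hidden: list[int] = field(default_factory=lambda: [256])
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.activation != "relu":
            raise ValueError("only the rectifier activation is supported")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    An epoch is one shuffled pass over the larger modality; the smaller one
    is cycled (reshuffled and repeated) so every minibatch holds
    ``batch_size`` cells from each stream.
    """

    batch_size: int = 256
    epochs: int = 150
    learning_rate: float = 1e-3
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    k0: int = 15
    optimizer: str = "adam"  # "adam" or "sgd"
    momentum: float = 0.9
    normalize: bool = True
    normalize_scale: float = 1e4
    cycle: bool = True
    novel_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if isinstance(self.weights, dict):
            self.weights = LossWeights(**self.weights)


# ------------------------------------------------------------------ networks
def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(config: ModelConfig, seed: int) -> dict[str, list[Tensor]]:
    """Deterministically initialize encoder and classifier parameters."""
    rng = np.random.default_rng([abs(int(seed)) % (2**31), 0])
    widths = [config.input_dim, *config.encoder_hidden, config.embed_dim]
    encoder = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        encoder.append(Tensor(_glorot(rng, fan_in, fan_out), requires_grad=True))
        encoder.append(Tensor(np.zeros(fan_out), requires_grad=True))
    classifier = [
        Tensor(_glorot(rng, config.embed_dim, config.n_classes), requires_grad=True),
        Tensor(np.zeros(config.n_classes), requires_grad=True),
    ]
    return {"encoder": encoder, "classifier": classifier}


def encode(params: dict, x: Tensor | np.ndarray) -> Tensor:
    """Run the encoder: affine layers with rectifier between hidden layers."""
    h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    layers = params["encoder"]
    n_layers = len(layers) // 2
    for i in range(n_layers):
        h = h @ layers[2 * i] + layers[2 * i + 1]
        if i < n_layers - 1:
            h = h.relu()
    return h


def classify(params: dict, h: Tensor) -> Tensor:
    w, b = params["classifier"]
    return h @ w + b


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class _Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(_Optimizer):
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr, momentum=0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.value = p.value - self.lr * v


class Adam(_Optimizer):
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.value = p.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ------------------------------------------------------------------- sampling
def epoch_minibatches(
    n_ref: int,
    n_target: int,
    batch_size: int,
    rng: np.random.Generator,
    cycle: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index batches for one epoch of two-stream training.

    One epoch is a shuffled pass over the larger modality; the smaller
    modality is cycled through reshuffled permutations so each of its cells
    appears as uniformly as possible.  Trailing partial batches are dropped:
    every batch holds exactly ``batch_size`` indices from each stream.
    """
    if n_ref < 1 or n_target < 1:
        raise ValueError("both modalities must be non-empty")
    if not cycle and batch_size > min(n_ref, n_target):
        raise ValueError(
            f"batch_size={batch_size} exceeds the smaller modality "
            f"({min(n_ref, n_target)} cells) and cycling is disabled"
        )

    n_major = max(n_ref, n_target)
    n_batches = max(n_major // batch_size, 1) if batch_size <= n_major else 0
    if n_batches == 0:
        raise ValueError("batch_size larger than both modalities")

    def stream(n: int) -> np.ndarray:
        """`n_batches * batch_size` indices from shuffled cycles over n cells."""
        needed = n_batches * batch_size
        reps = []
        while sum(len(r) for r in reps) < needed:
            reps.append(rng.permutation(n))
        return np.concatenate(reps)[:needed]

    ref_stream = stream(n_ref)
    target_stream = stream(n_target)
    return [
        (
            ref_stream[i * batch_size : (i + 1) * batch_size],
            target_stream[i * batch_size : (i + 1) * batch_size],
        )
        for i in range(n_batches)
    ]


# ------------------------------------------------------------------ the model
class CrossModalLabelTransfer:
    """Cross-modal label transfer from labeled reference to unlabeled target.

    Parameters
    ----------
    reference
        Labeled gene-expression dataset (GEM from scRNA-seq).
    target
        Unlabeled gene-activity dataset (GAM from scATAC-seq), sharing genes
        with the reference.
    target_rep
        Low-dimensional coordinates of the target cells' raw features (e.g.
        principal components of the peak matrix); the neighborhood graph
        that the contrastive loss preserves is built here, not in gene space.
    model_config, train_config
        Architecture and optimization settings; sensible defaults are
        derived from the data when omitted.
    """

    def __init__(
        self,
        reference: ExpressionDataset,
        target: ExpressionDataset,
        target_rep: LowDimRep,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> None:
        if reference.labels is None:
            raise ValueError("reference dataset must carry cell-type labels")
        target_rep.check_aligned(target)

        reference, target = align_genes(reference, target)
        self.train_config = train_config or TrainConfig()
        if self.train_config.normalize:
            reference = normalize_log_cpm(reference, self.train_config.normalize_scale)
            target = normalize_log_cpm(target, self.train_config.normalize_scale)
        self.reference = reference
        self.target = target
        self.target_rep = target_rep

        self.vocab, self._ref_codes = encode_labels(reference.labels)
        self.model_config = model_config or ModelConfig(
            input_dim=reference.n_genes, n_classes=self.vocab.n_classes
        )
        if self.model_config.input_dim != reference.n_genes:
            raise ValueError(
                f"model input_dim={self.model_config.input_dim} does not match "
                f"the {reference.n_genes} shared genes"
            )
        if self.model_config.n_classes != self.vocab.n_classes:
            raise ValueError("model n_classes does not match the reference label set")

        self._x_ref = reference.to_dense()
        self._x_target = target.to_dense()
        self.knn_graph: KnnGraph | None = None

    # ------------------------------------------------------------------ train
    def _train_step(
        self,
        params: dict,
        optimizer: _Optimizer,
        ref_idx: np.ndarray,
        target_idx: np.ndarray,
        partner_idx: np.ndarray,
        weights: LossWeights,
    ) -> dict[str, float]:
        """One gradient update on a pair of minibatches.

        The supervised loss reaches encoder and classifier; the three
        regularizers consume embeddings only, so their gradients stop at the
        encoder by construction.
        """
        h_ref = encode(params, self._x_ref[ref_idx])
        h_target = encode(params, self._x_target[target_idx])
        h_partner = encode(params, self._x_target[partner_idx])
        logits = classify(params, h_ref)

        ce = ce_loss_from_logits(logits, self._ref_codes[ref_idx])
        pr = pr_loss(h_ref, h_target)
        fa = fa_loss(h_target, h_ref, weights.top_p)
        ncl = ncl_loss(h_target, h_partner, weights.tau)
        objective = total_loss(ce, pr, fa, ncl, weights)

        record = {
            "ce": float(ce.value),
            "pr": float(pr.value),
            "fa": float(fa.value),
            "ncl": float(ncl.value),
            "total": float(objective.value),
        }
        bad = [k for k, v in record.items() if not np.isfinite(v)]
        if bad:
            raise FloatingPointError(f"non-finite loss component(s): {', '.join(bad)}")

        optimizer.zero_grad()
        objective.backward()
        optimizer.step()
        return record

    def fit(self) -> "LabelTransferResults":
        """Train the encoder and classifier by minibatch gradient descent.

        Builds the raw-feature kNN graph once, then runs
        ``epochs x batches`` steps of the combined objective.  All
        randomness (initialization, shuffling, neighbor sampling) derives
        from ``train_config.seed``.
        """
        tc = self.train_config
        if self.knn_graph is None:
            self.knn_graph = build_knn_graph(self.target_rep, tc.k0)

        params = init_parameters(self.model_config, tc.seed)
        all_params = params["encoder"] + params["classifier"]
        if tc.optimizer == "adam":
            optimizer: _Optimizer = Adam(all_params, tc.learning_rate)
        else:
            optimizer = SGD(all_params, tc.learning_rate, tc.momentum)
        rng = np.random.default_rng([abs(int(tc.seed)) % (2**31), 1])

        steps: list[dict] = []
        for epoch in range(tc.epochs):
            batches = epoch_minibatches(
                self.reference.n_cells, self.target.n_cells, tc.batch_size, rng, tc.cycle
            )
            for step, (ref_idx, target_idx) in enumerate(batches):
                partner_idx = sample_positive_partners(self.knn_graph, target_idx, rng)
                record = self._train_step(
                    params, optimizer, ref_idx, target_idx, partner_idx, tc.weights
                )
                steps.append({"epoch": epoch, "step": step, **record})

        history = pd.DataFrame(steps)
        return LabelTransferResults(
            params=params,
            model_config=self.model_config,
            train_config=tc,
            vocab=self.vocab,
            history=history,
            gene_names=list(self.reference.gene_names),
            model=self,
        )


@dataclass
class LabelTransferResults:
    """Fitted parameters plus prediction, evaluation and persistence."""

    params: dict
    model_config: ModelConfig
    train_config: TrainConfig
    vocab: LabelVocabulary
    history: pd.DataFrame
    gene_names: list[str] | None = None
    model: CrossModalLabelTransfer | None = None

    # ------------------------------------------------------------ prediction
    def predict(self, ds: ExpressionDataset | None = None):
        """Per-cell class probabilities, confidence and embedding.

        With no argument, predicts the target cells the model was built
        from (already gene-aligned and normalized); an explicit dataset is
        aligned to the model's gene space first.
        """
        from .evaluate import PredictionResult

        if ds is None:
            if self.model is None:
                raise ValueError("no attached training data; pass a dataset explicitly")
            x = self.model._x_target
            cell_ids = self.model.target.cell_ids
        else:
            x, cell_ids = self._prepare(ds)
        h = encode(self.params, x)
        logits = classify(self.params, h)
        probs = _softmax(logits.value)
        return PredictionResult(
            probabilities=probs,
            embedding=h.value,
            cell_ids=list(cell_ids),
        )

    def _prepare(self, ds: ExpressionDataset) -> tuple[np.ndarray, list[str]]:
        expected = self.gene_names
        if expected is None:
            raise ValueError("results carry no gene list; cannot align the dataset")
        missing = set(expected) - set(ds.gene_names)
        if missing:
            raise ValueError(
                f"dataset lacks {len(missing)} of the model's {len(expected)} genes "
                f"(e.g. {sorted(missing)[:3]})"
            )
        ds = ds.subset_genes(expected)
        if self.train_config.normalize:
            ds = normalize_log_cpm(ds, self.train_config.normalize_scale)
        return ds.to_dense(), ds.cell_ids

    def evaluate(self, truth_labels: list[str], ds: ExpressionDataset | None = None):
        """Score predictions against ground-truth labels.

        Truth labels outside the reference vocabulary count as novel ground
        truth; common-type accuracy and per-type F1 are computed on the rest,
        and novel-type AUROC / OSCR on the confidence scores.
        """
        from .evaluate import evaluate_predictions

        pred = self.predict(ds)
        return evaluate_predictions(pred, truth_labels, self.vocab)

    # ------------------------------------------------------------- reporting
    @property
    def epoch_history(self) -> pd.DataFrame:
        """Mean loss components per epoch."""
        return self.history.groupby("epoch")[["ce", "pr", "fa", "ncl", "total"]].mean()

    def summary(self) -> str:
        eh = self.epoch_history
        lines = [
            "Cross-modal label transfer — fit summary",
            "=" * 48,
            f"genes (M):            {self.model_config.input_dim}",
            f"embedding dim (d):    {self.model_config.embed_dim}",
            f"classes (K):          {self.model_config.n_classes}",
            f"encoder hidden:       {self.model_config.encoder_hidden or 'none (linear)'}",
            f"optimizer:            {self.train_config.optimizer} "
            f"(lr={self.train_config.learning_rate})",
            f"epochs x batches:     {self.train_config.epochs} x "
            f"{len(self.history) // max(self.train_config.epochs, 1)}",
            f"neighborhood size k0: {self.train_config.k0}",
            f"loss weights:         pr={self.train_config.weights.pr_weight} "
            f"lambda1={self.train_config.weights.lambda1} "
            f"lambda2={self.train_config.weights.lambda2} "
            f"tau={self.train_config.weights.tau} p={self.train_config.weights.top_p}",
            "-" * 48,
            f"first-epoch loss:     {eh['total'].iloc[0]:.4f}",
            f"final-epoch loss:     {eh['total'].iloc[-1]:.4f}",
            f"final CE/PR/FA/NCL:   {eh['ce'].iloc[-1]:.4f} / {eh['pr'].iloc[-1]:.4f} / "
            f"{eh['fa'].iloc[-1]:.4f} / {eh['ncl'].iloc[-1]:.4f}",
            f"classes:              {', '.join(self.vocab.classes)}",
        ]
        return "\n".join(lines)

    # ----------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Write a single-archive checkpoint (parameters + configs + vocab)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, p in enumerate(self.params["encoder"]):
            arrays[f"encoder_{i}"] = p.value
        for i, p in enumerate(self.params["classifier"]):
            arrays[f"classifier_{i}"] = p.value
        meta = {
            "model_config": asdict(self.model_config),
            "train_config": asdict(self.train_config),
            "classes": self.vocab.classes,
            "gene_names": self.gene_names,
            "history": self.history.to_dict(orient="list"),
        }
        np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LabelTransferResults":
        with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path,
                     allow_pickle=False) as archive:
            meta = json.loads(str(archive["_meta"]))
            n_enc = sum(1 for k in archive.files if k.startswith("encoder_"))
            n_cls = sum(1 for k in archive.files if k.startswith("classifier_"))
            params = {
                "encoder": [Tensor(archive[f"encoder_{i}"], requires_grad=True)
                            for i in range(n_enc)],
                "classifier": [Tensor(archive[f"classifier_{i}"], requires_grad=True)
                               for i in range(n_cls)],
            }
        tc = dict(meta["train_config"])
        tc["weights"] = LossWeights(**tc["weights"])
        return cls(
            params=params,
            model_config=ModelConfig(**meta["model_config"]),
            train_config=TrainConfig(**tc),
            vocab=LabelVocabulary(list(meta["classes"])),
            history=pd.DataFrame(meta["history"]),
            gene_names=meta.get("gene_names"),
            model=None,
        )
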