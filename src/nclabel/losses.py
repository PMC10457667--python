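"""Training losses for cross-modal label transfer.

Four losses shape the shared embedding space:

* **Projection regularization (PR)** — an asymmetric pairing of the
  neighborhood-and-dimension regularizer (NNDR): the full form (variance +
  orthogonality + zero-mean terms) on the target (scATAC) batch, and a
  reduced form without the variance term on the reference (scRNA) batch,
  whose variance already grows under the supervised loss.
* **Feature alignment (FA)** — negative mean cosine similarity over the
  top-p fraction of target cells best matched to some reference cell.
* **Cross-entropy (CE)** — standard supervised loss on the labeled
  reference cells.
* **Neighborhood-contrastive (NCL)** — a two-sided temperature-scaled
  contrastive loss pulling each target cell toward a sampled raw-feature
  neighbor and away from the other cells in the batch.

All losses are implemented once over :class:`~nclabel.autodiff.Tensor`;
passing plain arrays returns plain floats, passing tensors keeps the
computation on the tape so gradients flow to the encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "EmbeddingBatch",
    "LossWeights",
    "nndr_loss",
    "nndr_reduced_loss",
    "pr_loss",
    "fa_loss",
    "ce_loss",
    "ce_loss_from_logits",
    "ncl_loss",
    "total_loss",
]

_MAD_EPS = 1e-8  # guard for the inverted mean-absolute-deviation term
_NORM_EPS = 1e-12  # below this an embedding row counts as zero-norm


@dataclass
class EmbeddingBatch:
    """A batch of d-dimensional cell embeddings with derived statistics."""

    embeddings: np.ndarray

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be a batch x d matrix")

    @property
    def mean_vector(self) -> np.ndarray:
        return self.embeddings.mean(axis=0)

    @property
    def correlation_matrix(self) -> np.ndarray:
        """Pearson correlation across the batch; zero-variance dims -> 0."""
        centered = self.embeddings - self.mean_vector
        ss = (centered**2).sum(axis=0)
        active = ss > _NORM_EPS
        denom = np.sqrt(np.where(active, ss, 1.0))
        corr = (centered.T @ centered) / np.outer(denom, denom)
        corr *= np.outer(active, active)
        return corr


@dataclass
class LossWeights:
    """Weights and constants of the combined objective.

    ``pr_weight`` multiplies the projection regularizer (0.1 by default),
    ``lambda1``/``lambda2`` weight the alignment and contrastive terms,
    ``tau`` is the contrastive temperature and ``top_p`` the fraction of
    best-matched target cells entering the alignment loss.
    """

    pr_weight: float = 0.1
    lambda1: float = 1.0
    lambda2: float = 1.0
    tau: float = 0.2
    top_p: float = 0.8

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.top_p <= 1:
            raise ValueError("top_p must lie in (0, 1]")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, EmbeddingBatch):
        x = x.embeddings
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _ret(out: Tensor, keep: bool):
    return out if keep else float(out.value)


def _validate_batch(h: Tensor, need_d2: bool = True) -> None:
    if h.ndim != 2 or h.shape[0] < 2:
        raise ValueError("batch must contain at least 2 embeddings")
    if need_d2 and h.shape[1] < 2:
        raise ValueError("embedding dimension must be >= 2")


def _nndr_terms(h: Tensor, with_term1: bool = True) -> tuple[Tensor | None, Tensor, Tensor]:
    """The three NNDR components: inverse-MAD, off-diagonal |corr|, |mean|."""
    n, d = h.shape
    hbar = h.mean(axis=0, keepdims=True)
    centered = h - hbar

    term1 = None
    if with_term1:
        mad = centered.abs().mean()
        if mad.value < 1e-10:
            warnings.warn(
                "degenerate embedding batch (all rows identical): "
                "inverse-variability term is epsilon-guarded",
                RuntimeWarning,
                stacklevel=3,
            )
        term1 = 1.0 / (mad + _MAD_EPS)

    ss = (centered * centered).sum(axis=0)  # (d,)
    active = ss.value > _NORM_EPS
    denom = (ss + Tensor(np.where(active, 0.0, 1.0))).sqrt()
    corr = (centered.T @ centered) / (denom.reshape(d, 1) * denom.reshape(1, d))
    offdiag = (1.0 - np.eye(d)) * np.outer(active, active)
    term2 = (corr.abs() * Tensor(offdiag)).sum() / (d * d)

    term3 = hbar.abs().sum() / d
    return term1, term2, term3


def nndr_loss(batch) -> float | Tensor:
    """Full NNDR regularizer: variability + orthogonality + zero-mean terms."""
    h, keep = _as_tensor(batch)
    _validate_batch(h)
    t1, t2, t3 = _nndr_terms(h)
    return _ret(t1 + t2 + t3, keep)


def nndr_reduced_loss(batch) -> float | Tensor:
    """NNDR without the inverse-variability term (used on the labeled batch)."""
    h, keep = _as_tensor(batch)
    _validate_batch(h)
    _, t2, t3 = _nndr_terms(h, with_term1=False)
    return _ret(t2 + t3, keep)


def pr_loss(rna_batch, atac_batch) -> float | Tensor:
    """Projection regularization: full NNDR on the target batch plus the
    reduced form on the reference batch."""
    rna, keep_r = _as_tensor(rna_batch)
    atac, keep_a = _as_tensor(atac_batch)
    _validate_batch(rna)
    _validate_batch(atac)
    t1u, t2u, t3u = _nndr_terms(atac)
    _, t2l, t3l = _nndr_terms(rna, with_term1=False)
    return _ret(t1u + t2u + t3u + t2l + t3l, keep_r or keep_a)


def _row_normalize(h: Tensor, on_zero: str) -> Tensor:
    """Scale rows to unit L2 norm; zero rows stay zero (warn) or error."""
    norms_sq = (h * h).sum(axis=1, keepdims=True)
    zero_rows = norms_sq.value[:, 0] <= _NORM_EPS
    if zero_rows.any():
        if on_zero == "error":
            raise ValueError("zero-norm embedding row in contrastive loss")
        warnings.warn(
            "zero-norm embedding rows treated as similarity 0 in alignment loss",
            RuntimeWarning,
            stacklevel=3,
        )
    safe = norms_sq + Tensor(np.where(zero_rows, 1.0, 0.0)[:, None])
    hn = h / safe.sqrt()
    if zero_rows.any():
        hn = hn * Tensor((~zero_rows).astype(float)[:, None])
    return hn


def fa_loss(atac_batch, rna_batch, top_p: float = 0.8) -> float | Tensor:
    """Feature alignment: for each target cell find its best-matching
    reference cell by cosine similarity, then average the negative cosine
    over the top-p fraction of target cells with the highest best-match
    scores.  Ties (in the argmax and in the top-p cut) resolve to the lowest
    index."""
    if not 0 < top_p <= 1:
        raise ValueError("top_p must lie in (0, 1]")
    atac, keep_a = _as_tensor(atac_batch)
    rna, keep_r = _as_tensor(rna_batch)
    if atac.shape[0] < 1 or rna.shape[0] < 1:
        raise ValueError("batches must be non-empty")

    atac_n = _row_normalize(atac, on_zero="warn")
    rna_n = _row_normalize(rna, on_zero="warn")
    sims = atac_n @ rna_n.T  # (Nu, Nl) cosine similarities

    best_idx = np.argmax(sims.value, axis=1)  # lowest index on ties
    best_vals = sims.value[np.arange(sims.shape[0]), best_idx]
    n_keep = int(np.ceil(top_p * sims.shape[0]))
    # stable sort on -similarity keeps ascending-index order among ties
    selected = np.argsort(-best_vals, kind="stable")[:n_keep]

    chosen = sims.take_rows(selected, best_idx[selected])
    return _ret(-chosen.mean(), keep_a or keep_r)


def ce_loss(probabilities, labels) -> float | Tensor:
    """Mean negative log-probability of the true class, from simplex rows."""
    probs, keep = _as_tensor(probabilities)
    labels = np.asarray(labels, dtype=np.int64)
    if not np.allclose(probs.value.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError(f"label code out of range 0..{probs.shape[1] - 1}")
    picked = probs.take_rows(np.arange(probs.shape[0]), labels)
    return _ret(-picked.log().mean(), keep)


def ce_loss_from_logits(logits, labels) -> float | Tensor:
    """Numerically stable cross-entropy straight from classifier logits."""
    z, keep = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= z.shape[1]:
        raise ValueError(f"label code out of range 0..{z.shape[1] - 1}")
    shift = np.max(z.value, axis=1, keepdims=True)
    shifted = z - Tensor(shift)
    log_norm = shifted.exp().sum(axis=1, keepdims=True).log()
    log_probs = shifted - log_norm
    picked = log_probs.take_rows(np.arange(z.shape[0]), labels)
    return _ret(-picked.mean(), keep)


def ncl_loss(atac_embeddings, partner_embeddings, tau: float = 0.2) -> float | Tensor:
    """Two-sided neighborhood-contrastive loss.

    With sigma(a, b) = exp(cos(a, b) / tau), each anchor h_b is contrasted
    against its sampled-neighbor partner hhat_b: the positive similarity is
    normalized by the anchor's similarity to all partners plus all other
    anchors, and symmetrically for the partner side.  The value is the mean
    negative log of those two normalized fractions, halved; it is always
    >= 0 because each numerator also appears in its denominator.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    h, keep_h = _as_tensor(atac_embeddings)
    hh, keep_p = _as_tensor(partner_embeddings)
    if h.shape != hh.shape:
        raise ValueError("anchor and partner batches must have identical shape")
    n = h.shape[0]
    if n < 1:
        raise ValueError("batch must be non-empty")

    hn = _row_normalize(h, on_zero="error")
    hhn = _row_normalize(hh, on_zero="error")

    s_cross = (hn @ hhn.T) / tau  # s_cross[b, r] = cos(h_b, hhat_r)/tau
    s_hh = (hn @ hn.T) / tau
    s_pp = (hhn @ hhn.T) / tau

    offdiag = Tensor(1.0 - np.eye(n))
    diag_idx = np.arange(n)
    pos = s_cross.take_rows(diag_idx, diag_idx)  # <h_b, hhat_b>: same both ways

    d1 = s_cross.exp().sum(axis=1) + (s_hh.exp() * offdiag).sum(axis=1)
    d2 = s_cross.T.exp().sum(axis=1) + (s_pp.exp() * offdiag).sum(axis=1)
    loss = -((pos - d1.log()) + (pos - d2.log())).sum() / (2 * n)
    return _ret(loss, keep_h or keep_p)


def total_loss(ce, pr, fa, ncl, weights: LossWeights) -> float | Tensor:
    """Combined objective: CE + pr_weight*PR + lambda1*FA + lambda2*NCL."""
    return ce + weights.pr_weight * pr + weights.lambda1 * fa + weights.lambda2 * ncl
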