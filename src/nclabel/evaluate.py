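"""Predictions, confidence-based novel-type calling, and evaluation metrics.

A trained classifier yields a K-class probability vector r per target cell.
The predicted type is argmax_k r(k), its confidence e = max_k r(k), and the
confidence that the cell belongs to a type absent from the reference is
e_novel = 1 - e.  Evaluation reports common-type accuracy, per-type F1,
novel-type AUROC (rank statistic on e_novel) and OSCR, the area under the
correct-classification rate vs false-positive rate curve as a confidence
threshold varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import LabelVocabulary

__all__ = [
    "PredictionResult",
    "EvalReport",
    "call_novel",
    "common_type_accuracy",
    "per_type_f1",
    "novel_auroc",
    "oscr",
    "evaluate_predictions",
    "confidence_histogram",
]


@dataclass
class PredictionResult:
    """Per-cell probabilities and derived quantities.

    ``predicted_code`` attains each row's maximum probability (ties resolve
    to the lowest class code); ``confidence`` is that maximum and
    ``novel_confidence`` its complement.
    """

    probabilities: np.ndarray  # (cells, K), simplex rows
    cell_ids: list[str]
    embedding: np.ndarray | None = None
    predicted_code: np.ndarray = field(init=False)
    confidence: np.ndarray = field(init=False)
    novel_confidence: np.ndarray = field(init=False)
    novel_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.ndim != 2:
            raise ValueError("probabilities must be cells x K")
        if len(self.probabilities) and not np.allclose(
            self.probabilities.sum(axis=1), 1.0, atol=1e-6
        ):
            raise ValueError("probability rows must sum to 1")
        if len(self.cell_ids) != self.probabilities.shape[0]:
            raise ValueError("cell_ids length does not match probabilities")
        self.predicted_code = (
            np.argmax(self.probabilities, axis=1)
            if len(self.probabilities)
            else np.empty(0, dtype=np.int64)
        )
        self.confidence = (
            self.probabilities.max(axis=1) if len(self.probabilities) else np.empty(0)
        )
        self.novel_confidence = 1.0 - self.confidence

    @property
    def n_cells(self) -> int:
        return self.probabilities.shape[0]


def call_novel(result: PredictionResult, threshold: float = 0.5) -> np.ndarray:
    """Flag cells whose known-type confidence falls strictly below threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    flags = result.confidence < threshold
    result.novel_flags = flags
    return flags


def _common_mask(true_labels: list[str], vocab: LabelVocabulary) -> np.ndarray:
    """Cells whose true label is in the reference vocabulary (not novel)."""
    return np.array([y in vocab for y in true_labels], dtype=bool)


def common_type_accuracy(
    true_labels: list[str], predicted_codes: np.ndarray, vocab: LabelVocabulary
) -> float | None:
    """Fraction of correctly classified cells among common-type cells.

    Cells whose true label is outside the reference vocabulary are novel
    ground truth and excluded from the denominator.  Returns None when no
    common-type cells exist.
    """
    mask = _common_mask(true_labels, vocab)
    if not mask.any():
        return None
    true_codes = vocab.encode([y for y, m in zip(true_labels, mask) if m])
    return float(np.mean(np.asarray(predicted_codes)[mask] == true_codes))


def per_type_f1(
    true_labels: list[str], predicted_codes: np.ndarray, vocab: LabelVocabulary
) -> dict[str, float]:
    """F1 per cell type over common-type cells.

    A class that is never predicted and never true among the evaluated cells
    is absent from the result; a class with zero precision or recall
    denominator gets F1 = 0.
    """
    mask = _common_mask(true_labels, vocab)
    predicted_codes = np.asarray(predicted_codes)[mask]
    true_codes = vocab.encode([y for y, m in zip(true_labels, mask) if m])
    scores: dict[str, float] = {}
    for code, name in enumerate(vocab.classes):
        tp = int(np.sum((predicted_codes == code) & (true_codes == code)))
        fp = int(np.sum((predicted_codes == code) & (true_codes != code)))
        fn = int(np.sum((predicted_codes != code) & (true_codes == code)))
        if tp + fp + fn == 0:
            continue  # class absent from this evaluation
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        scores[name] = (
            2 * precision * recall / (precision + recall) if precision + recall else 0.0
        )
    return scores


def novel_auroc(novel_confidences: np.ndarray, is_novel_truth: np.ndarray) -> float | None:
    """AUROC for novel-vs-common separation by the novel confidence.

    Mann-Whitney formulation: the probability that a random novel cell
    scores higher than a random common cell, ties counting one half.
    Returns None if either group is empty.
    """
    scores = np.asarray(novel_confidences, dtype=np.float64)
    truth = np.asarray(is_novel_truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 credit
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def oscr(
    confidences: np.ndarray,
    predicted_codes: np.ndarray,
    true_labels: list[str],
    is_novel_truth: np.ndarray,
    vocab: LabelVocabulary,
) -> float | None:
    """Open-set classification rate.

    Sweeping a threshold theta over confidence values, CCR(theta) is the
    fraction of common cells that are correctly classified with confidence
    strictly above theta, and FPR(theta) the fraction of novel cells with
    confidence strictly above theta.  The area under CCR vs FPR reduces to
    the mean over novel cells j of CCR evaluated at theta = e_j.
    """
    confidences = np.asarray(confidences, dtype=np.float64)
    truth = np.asarray(is_novel_truth, dtype=bool)
    if truth.sum() == 0 or (~truth).sum() == 0:
        return None

    common = ~truth
    common_conf = confidences[common]
    common_pred = np.asarray(predicted_codes)[common]
    common_true = vocab.encode([y for y, m in zip(true_labels, common) if m])
    correct = common_pred == common_true

    novel_conf = confidences[truth]
    n_common = common_conf.shape[0]
    # CCR(theta) for each novel threshold, vectorized by sorting the
    # correct common confidences
    correct_conf = np.sort(common_conf[correct])
    ccr = (correct_conf.size - np.searchsorted(correct_conf, novel_conf, side="right")) / n_common
    return float(ccr.mean())


@dataclass
class EvalReport:
    """Summary of a label-transfer evaluation."""

    common_accuracy: float | None
    per_type_f1: dict[str, float]
    novel_auroc: float | None
    oscr: float | None
    n_common: int
    n_novel: int

    def to_dict(self) -> dict:
        out = {
            "common_accuracy": self.common_accuracy,
            "per_type_f1": self.per_type_f1,
            "n_common": self.n_common,
            "n_novel": self.n_novel,
        }
        if self.novel_auroc is not None:
            out["novel_auroc"] = self.novel_auroc
        if self.oscr is not None:
            out["oscr"] = self.oscr
        return out

    @property
    def macro_f1(self) -> float | None:
        return float(np.mean(list(self.per_type_f1.values()))) if self.per_type_f1 else None


def evaluate_predictions(
    result: PredictionResult, true_labels: list[str], vocab: LabelVocabulary
) -> EvalReport:
    """Full evaluation of a prediction against ground truth.

    Truth labels not found in the reference vocabulary define novel ground
    truth; novelty metrics are reported only when both groups are present.
    """
    if len(true_labels) != result.n_cells:
        raise ValueError("true_labels length does not match predictions")
    mask = _common_mask(true_labels, vocab)
    is_novel = ~mask
    return EvalReport(
        common_accuracy=common_type_accuracy(true_labels, result.predicted_code, vocab),
        per_type_f1=per_type_f1(true_labels, result.predicted_code, vocab),
        novel_auroc=novel_auroc(result.novel_confidence, is_novel),
        oscr=oscr(result.confidence, result.predicted_code, true_labels, is_novel, vocab),
        n_common=int(mask.sum()),
        n_novel=int(is_novel.sum()),
    )


def confidence_histogram(
    confidences: np.ndarray, is_novel_truth: np.ndarray, n_bins: int = 20
) -> dict:
    """Histogram summary of confidence by truth group (density-plot support)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    truth = np.asarray(is_novel_truth, dtype=bool)
    common_counts, _ = np.histogram(np.asarray(confidences)[~truth], bins=edges)
    novel_counts, _ = np.histogram(np.asarray(confidences)[truth], bins=edges)
    return {
        "bin_edges": edges.tolist(),
        "common_counts": common_counts.tolist(),
        "novel_counts": novel_counts.tolist(),
    }
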