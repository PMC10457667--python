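"""Linked two-modality synthetic benchmarks with known ground truth.

Cells of each type are drawn from an isotropic Gaussian cluster in a shared
latent space.  The reference modality (a labeled GEM) renders latent states
through a gene loading matrix.  The target modality is rendered in two
stages mimicking scATAC-seq processing: a wide binary raw-feature matrix
(peak-like accessibility calls, several features per gene, correlated with
that gene's loading) from which a low-dimensional representation is
computed, and a gene-level activity matrix (GAM) obtained by aggregating
raw features per gene.  A ``distortion`` parameter mixes the faithful
aggregation with a rank-deficient scramble, so the GAM loses raw-space
neighborhood information as distortion grows — the failure mode the
neighborhood-contrastive regularizer exists to counteract.  Novel cell
types appear only in the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .io import ExpressionDataset, LowDimRep, write_mtx_dataset

__all__ = [
    "SyntheticConfig",
    "simulate_latent_cells",
    "render_reference_modality",
    "render_target_modality",
    "make_benchmark",
    "write_benchmark",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    ``noise_sd`` is the within-type latent spread (the biological
    cell-to-cell variability both modalities share); ``obs_noise_sd`` is
    modality-specific measurement noise on the reference rendering;
    ``distortion`` in [0, 1] controls how much of the gene-activity signal
    is replaced by a rank-deficient scramble; ``dropout_rate`` zeroes
    observed entries at random in the target modality.
    """

    n_common_types: int = 3
    n_novel_types: int = 1
    cells_per_type_ref: int = 200
    cells_per_type_target: int = 300
    n_genes: int = 200
    n_raw_features: int = 2000
    latent_dim: int = 10
    noise_sd: float = 1.0
    obs_noise_sd: float = 0.1
    type_separation: float = 6.0
    within_amplitude: float = 2.0
    within_decay: float = 0.35
    loading_jitter: float = 0.2
    distortion: float = 0.3
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_common_types < 2:
            raise ValueError("need at least 2 common types")
        if self.n_novel_types < 0:
            raise ValueError("n_novel_types must be >= 0")
        if not 0 <= self.distortion <= 1:
            raise ValueError("distortion must lie in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.latent_dim < self.n_common_types + self.n_novel_types:
            raise ValueError("latent_dim must be >= total number of types")
        if self.n_raw_features < self.n_genes:
            raise ValueError("n_raw_features must be >= n_genes")
        if self.noise_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def n_types(self) -> int:
        return self.n_common_types + self.n_novel_types

    def type_names(self) -> list[str]:
        return [f"type_{i}" for i in range(self.n_common_types)] + [
            f"novel_{i}" for i in range(self.n_novel_types)
        ]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(config.seed)) % (2**31), stream])


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _type_means(config: SyntheticConfig) -> np.ndarray:
    """Cluster centers: random orthonormal directions scaled to a fixed
    separation, so inter-type distances are controlled and identical for
    every modality."""
    rng = _rng(config, 0)
    basis, _ = np.linalg.qr(rng.standard_normal((config.latent_dim, config.latent_dim)))
    return basis[:, : config.n_types].T * config.type_separation  # (n_types, latent_dim)


def _type_shapes(config: SyntheticConfig) -> np.ndarray:
    """Per-type within-cluster covariance square roots.

    Within-type variation is anisotropic — a few dominant directions with a
    geometrically decaying spectrum, oriented at random per type — which
    mimics the low-dimensional continuous heterogeneity (activation states,
    differentiation gradients) seen inside real cell types.  The same shape
    is shared by both modalities, only the draws differ.
    """
    rng = _rng(config, 6)
    scales = config.within_amplitude * config.within_decay ** np.arange(config.latent_dim)
    shapes = np.empty((config.n_types, config.latent_dim, config.latent_dim))
    for t in range(config.n_types):
        q, _ = np.linalg.qr(rng.standard_normal((config.latent_dim, config.latent_dim)))
        shapes[t] = q * scales  # columns scaled: maps N(0, I) draws to the cluster shape
    return shapes


def simulate_latent_cells(
    config: SyntheticConfig, role: str = "target"
) -> tuple[np.ndarray, list[str]]:
    """Draw per-cell latent states for one modality.

    The reference contains only common types (``cells_per_type_ref`` cells
    each); the target contains common and novel types
    (``cells_per_type_target`` each).  Type means are shared across roles.
    """
    if role not in ("reference", "target"):
        raise ValueError("role must be 'reference' or 'target'")
    means = _type_means(config)
    shapes = _type_shapes(config)
    names = config.type_names()
    if role == "reference":
        n_types, n_per, stream = config.n_common_types, config.cells_per_type_ref, 1
    else:
        n_types, n_per, stream = config.n_types, config.cells_per_type_target, 2
    rng = _rng(config, stream)
    latent = np.vstack(
        [means[t]
         + config.noise_sd * rng.standard_normal((n_per, config.latent_dim)) @ shapes[t].T
         for t in range(n_types)]
    )
    labels = [names[t] for t in range(n_types) for _ in range(n_per)]
    return latent, labels


def _gene_loadings(config: SyntheticConfig) -> np.ndarray:
    """Shared latent -> gene loading basis used by both modalities."""
    rng = _rng(config, 3)
    return rng.standard_normal((config.latent_dim, config.n_genes)) / np.sqrt(config.latent_dim)


def _feature_gene_map(config: SyntheticConfig) -> np.ndarray:
    """Assign each raw feature to a gene (contiguous groups, remainder spread)."""
    return np.arange(config.n_raw_features) % config.n_genes


def render_reference_modality(
    latent: np.ndarray, labels: list[str], config: SyntheticConfig
) -> ExpressionDataset:
    """Render latent states into a labeled gene-expression matrix.

    Expression is a softplus-linear map of the latent state plus truncated
    Gaussian measurement noise, scaled by a lognormal per-cell library-size
    factor.
    """
    rng = _rng(config, 4)
    clean = _softplus(latent @ _gene_loadings(config) * 2.0)
    noisy = clean + config.obs_noise_sd * rng.standard_normal(clean.shape)
    np.clip(noisy, 0.0, None, out=noisy)
    library = rng.lognormal(mean=0.0, sigma=0.3, size=(latent.shape[0], 1))
    matrix = library * noisy
    cell_ids = [f"rna_{i:05d}" for i in range(latent.shape[0])]
    return ExpressionDataset(matrix, cell_ids, [f"gene_{j:04d}" for j in range(config.n_genes)],
                             list(labels))


def render_target_modality(
    latent: np.ndarray,
    labels: list[str],
    config: SyntheticConfig,
    return_raw: bool = False,
):
    """Render latent states into a raw binary feature matrix, its
    low-dimensional representation, and a gene-activity matrix.

    Raw features are peak-like Bernoulli calls whose activation probability
    follows the latent state through per-feature loadings correlated with
    the feature's gene.  The GAM aggregates each gene's features; with
    ``distortion`` > 0 a rank-deficient mixture replaces part of that
    faithful signal, scrambling gene-space neighborhoods while the raw
    features (and hence the low-dimensional representation) are untouched.
    Truth labels are returned separately — the dataset itself is unlabeled.
    """
    rng = _rng(config, 5)
    n_cells = latent.shape[0]
    gene_of = _feature_gene_map(config)
    w_gene = _gene_loadings(config)  # (latent_dim, n_genes)

    # per-feature loadings: the gene's loading direction plus feature jitter
    jitter = config.loading_jitter * rng.standard_normal(
        (config.latent_dim, config.n_raw_features)
    )
    w_raw = w_gene[:, gene_of] + jitter
    activity = _softplus(latent @ w_raw * 2.0)
    # binarize at staggered per-feature quantile thresholds: the features of
    # one gene form a graded (thermometer-like) code of its activity, the
    # way peaks of one locus open progressively with regulatory activity
    order = np.zeros(config.n_raw_features, dtype=np.int64)
    counts_per_gene: dict[int, int] = {}
    for f, g in enumerate(gene_of):
        order[f] = counts_per_gene.get(g, 0)
        counts_per_gene[g] = order[f] + 1
    n_per_gene = np.bincount(gene_of, minlength=config.n_genes)
    quantiles = (order + 1) / (n_per_gene[gene_of] + 1)
    sorted_act = np.sort(activity, axis=0)
    pos = quantiles * (n_cells - 1)
    lo = np.floor(pos).astype(np.int64)
    hi = np.ceil(pos).astype(np.int64)
    cols = np.arange(config.n_raw_features)
    frac = pos - lo
    thresholds = sorted_act[lo, cols] * (1.0 - frac) + sorted_act[hi, cols] * frac
    raw = (activity > thresholds).astype(np.float64)
    if config.dropout_rate > 0:
        raw *= rng.random(raw.shape) >= config.dropout_rate

    n_comp = min(50, config.n_raw_features, n_cells - 1)
    coords = PCA(n_components=n_comp, random_state=0).fit_transform(raw)

    # faithful gene-level view: mean accessibility of each gene's features
    counts = np.bincount(gene_of, minlength=config.n_genes).astype(np.float64)
    p_agg = np.zeros((config.n_raw_features, config.n_genes))
    p_agg[np.arange(config.n_raw_features), gene_of] = 1.0 / counts[gene_of]
    faithful = raw @ p_agg

    gam = faithful
    if config.distortion > 0:
        # rank-deficient scramble: collapses cells onto a 2-D gene-space
        # manifold, destroying fine neighborhood structure
        left = np.abs(rng.standard_normal((config.n_raw_features, 2)))
        right = np.abs(rng.standard_normal((2, config.n_genes)))
        scramble = raw @ (left / config.n_raw_features) @ right
        scale = faithful.std() / max(scramble.std(), 1e-12)
        gam = (1.0 - config.distortion) * faithful + config.distortion * scale * scramble
    if config.dropout_rate > 0:
        gam = gam * (rng.random(gam.shape) >= config.dropout_rate)

    cell_ids = [f"atac_{i:05d}" for i in range(n_cells)]
    gene_names = [f"gene_{j:04d}" for j in range(config.n_genes)]
    dataset = ExpressionDataset(gam, cell_ids, gene_names, labels=None)
    rep = LowDimRep(coords, cell_ids)
    if return_raw:
        return dataset, rep, list(labels), raw
    return dataset, rep, list(labels)


def make_benchmark(config: SyntheticConfig | None = None) -> dict:
    """Generate the full linked benchmark.

    Returns a dict with the labeled ``reference`` GEM, the unlabeled
    ``target`` GAM, the target's ``rep`` (low-dimensional raw-feature
    coordinates), the held-out ``truth_labels`` for evaluation, and a
    ``manifest`` echoing the configuration.
    """
    config = config or SyntheticConfig()
    latent_ref, labels_ref = simulate_latent_cells(config, role="reference")
    latent_tgt, labels_tgt = simulate_latent_cells(config, role="target")
    reference = render_reference_modality(latent_ref, labels_ref, config)
    target, rep, truth, raw = render_target_modality(
        latent_tgt, labels_tgt, config, return_raw=True
    )
    manifest = {
        "config": asdict(config),
        "n_reference_cells": reference.n_cells,
        "n_target_cells": target.n_cells,
        "common_types": config.type_names()[: config.n_common_types],
        "novel_types": config.type_names()[config.n_common_types :],
    }
    return {
        "reference": reference,
        "target": target,
        "rep": rep,
        "truth_labels": truth,
        "raw": raw,  # in-memory only: the binary raw-feature matrix
        "manifest": manifest,
        "latent_target": latent_tgt,
    }


def write_benchmark(benchmark: dict, outdir: str | Path) -> dict[str, Path]:
    """Write all benchmark artifacts (MTX + sidecars, CSV, TSV, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths.update({f"reference_{k}": v for k, v in
                  write_mtx_dataset(benchmark["reference"], outdir / "reference").items()})
    paths.update({f"target_{k}": v for k, v in
                  write_mtx_dataset(benchmark["target"], outdir / "target").items()})

    rep = benchmark["rep"]
    rep_path = outdir / "target_lowdim.csv"
    header = "cell_id," + ",".join(f"dim_{j}" for j in range(rep.coords.shape[1]))
    rows = (",".join([cid] + [f"{v:.10g}" for v in row])
            for cid, row in zip(rep.cell_ids, rep.coords))
    rep_path.write_text(header + "\n" + "\n".join(rows) + "\n")
    paths["rep"] = rep_path

    truth_path = outdir / "truth_labels.tsv"
    truth_path.write_text(
        "cell_id\ttrue_type\n"
        + "".join(f"{c}\t{y}\n" for c, y in zip(benchmark["target"].cell_ids,
                                                benchmark["truth_labels"]))
    )
    paths["truth"] = truth_path

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(benchmark["manifest"], indent=2) + "\n")
    paths["manifest"] = manifest_path
    return paths
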