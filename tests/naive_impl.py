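"""Independent naive (loop-based) reference implementations.

These deliberately avoid the package's vectorized code paths: plain Python
loops and scalar arithmetic only, so they can serve as oracles for the
production implementations.
"""

from __future__ import annotations

import math

import numpy as np

MAD_EPS = 1e-8


def nndr_naive(h: np.ndarray, with_term1: bool = True) -> float:
    n, d = h.shape
    hbar = [sum(h[b][j] for b in range(n)) / n for j in range(d)]
    total = 0.0
    if with_term1:
        mad = sum(abs(h[b][j] - hbar[j]) for b in range(n) for j in range(d)) / (n * d)
        total += 1.0 / (mad + MAD_EPS)
    # pearson correlation with zero-variance dims treated as correlation 0
    term2 = 0.0
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            ci = [h[b][i] - hbar[i] for b in range(n)]
            cj = [h[b][j] - hbar[j] for b in range(n)]
            ssi = sum(x * x for x in ci)
            ssj = sum(x * x for x in cj)
            if ssi <= 1e-12 or ssj <= 1e-12:
                continue
            term2 += abs(sum(a * b for a, b in zip(ci, cj)) / math.sqrt(ssi * ssj))
    total += term2 / (d * d)
    total += sum(abs(m) for m in hbar) / d
    return total


def pr_naive(rna: np.ndarray, atac: np.ndarray) -> float:
    return nndr_naive(atac, with_term1=True) + nndr_naive(rna, with_term1=False)


def _cos(a, b) -> float:
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(x * x for x in b))
    if na <= 1e-6 or nb <= 1e-6:
        return 0.0
    return sum(x * y for x, y in zip(a, b)) / (na * nb)


def fa_naive(atac: np.ndarray, rna: np.ndarray, top_p: float) -> float:
    n_u = len(atac)
    best = []
    for b in range(n_u):
        sims = [_cos(atac[b], rna[i]) for i in range(len(rna))]
        idx = max(range(len(rna)), key=lambda i: (sims[i], -i))  # lowest index on ties
        best.append((sims[idx], idx))
    n_keep = math.ceil(top_p * n_u)
    order = sorted(range(n_u), key=lambda b: (-best[b][0], b))[:n_keep]
    return -sum(best[b][0] for b in order) / n_keep


def ce_naive(probs: np.ndarray, labels) -> float:
    return -sum(math.log(probs[b][labels[b]]) for b in range(len(labels))) / len(labels)


def ncl_naive(h: np.ndarray, hh: np.ndarray, tau: float) -> float:
    n = len(h)

    def sigma(a, b):
        na = math.sqrt(sum(x * x for x in a))
        nb = math.sqrt(sum(x * x for x in b))
        return math.exp(sum(x * y for x, y in zip(a, b)) / (tau * na * nb))

    total = 0.0
    for b in range(n):
        d1 = sum(sigma(h[b], hh[r]) for r in range(n))
        d1 += sum(sigma(h[b], h[r]) for r in range(n) if r != b)
        d2 = sum(sigma(hh[b], h[r]) for r in range(n))
        d2 += sum(sigma(hh[b], hh[r]) for r in range(n) if r != b)
        total += math.log(sigma(h[b], hh[b]) / d1) + math.log(sigma(hh[b], h[b]) / d2)
    return -total / (2 * n)


def auroc_naive(scores: np.ndarray, is_pos: np.ndarray) -> float:
    pos = [s for s, p in zip(scores, is_pos) if p]
    neg = [s for s, p in zip(scores, is_pos) if not p]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oscr_naive(conf, pred, true_codes, is_novel) -> float:
    """Threshold-sweep oracle: mean over novel cells of CCR at their confidence."""
    common = [i for i, nv in enumerate(is_novel) if not nv]
    novel = [i for i, nv in enumerate(is_novel) if nv]
    total = 0.0
    for j in novel:
        theta = conf[j]
        ccr = sum(
            1 for i in common if pred[i] == true_codes[i] and conf[i] > theta
        ) / len(common)
        total += ccr
    return total / len(novel)


def knn_naive(coords: np.ndarray, k0: int) -> np.ndarray:
    """Exhaustive neighbor search with (distance, index) ordering."""
    n = len(coords)
    out = np.empty((n, k0), dtype=np.int64)
    for i in range(n):
        dists = [
            (float(np.sqrt(((coords[i] - coords[j]) ** 2).sum())), j)
            for j in range(n)
            if j != i
        ]
        dists.sort()
        out[i] = [j for _, j in dists[:k0]]
    return out
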