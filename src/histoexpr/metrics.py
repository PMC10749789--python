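"""Evaluation statistics: Pearson correlation, its p-value, gene ranking,
adjusted Rand index, and K-means clustering against annotations."""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import comb

__all__ = ["pcc", "pcc_pvalue", "rank_genes", "ari", "cluster_eval"]


def pcc(x_true, x_pred) -> float:
    """Pearson correlation Cov(x, y) / (σx σy) in [-1, 1].

    Returns NaN (flagged, to be excluded from means) when either side has
    zero variance or fewer than two observations.
    """
    x = np.asarray(x_true, dtype=float)
    y = np.asarray(x_pred, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 2:
        return float("nan")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc ** 2).mean())
    sy = np.sqrt((yc ** 2).mean())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float((xc * yc).mean() / (sx * sy))
    return max(-1.0, min(1.0, r))


def pcc_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r from n paired observations.

    t = r sqrt((n-2)/(1-r²)) against Student-t with n-2 df; |r| = 1 gives
    p = 0 by convention.
    """
    if n < 3:
        raise ValueError("p-value needs n >= 3")
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def rank_genes(gene_names, pvalues) -> list:
    """Genes sorted by mean −log10 p across sections, descending; ties by name.

    ``pvalues``: array-like (n_sections, n_genes) or (n_genes,); NaNs are
    ignored within a gene's mean.
    """
    p = np.atleast_2d(np.asarray(pvalues, dtype=float))
    if p.shape[1] != len(gene_names):
        raise ValueError("pvalue columns must match gene_names")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.clip(p, 1e-300, None))
    score = np.nanmean(neglog, axis=0)
    order = sorted(range(len(gene_names)),
                   key=lambda i: (-score[i], str(gene_names[i])))
    return [gene_names[i] for i in order]


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from the pair-counting contingency table.

    (Σ_ij C(n_ij,2) − E) / (max − E) with E = Σ_i C(a_i,2) Σ_j C(b_j,2) / C(n,2);
    two trivial identical partitions (one cluster each) give 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be equal-length 1-D label arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:       # both partitions trivial (or identical singletons)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def cluster_eval(pred_expr, annotations, k: int, seed: int = 0,
                 n_init: int = 10) -> float:
    """K-means on predicted expression, scored by ARI against annotations."""
    from sklearn.cluster import KMeans
    X = np.asarray(pred_expr, dtype=float)
    ann = np.asarray(annotations)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of spots {X.shape[0]}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(X)
    return ari(labels, ann)
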