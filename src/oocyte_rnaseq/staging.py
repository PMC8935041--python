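"""SN/NSN developmental staging of GV oocytes.

Supervised PCA on SN-featured genes (genes >2-fold higher in SN than NSN
oocytes in a reference bulk comparison), k-means clustering of the embedding
(k = 2 or 3, best of 25 random initializations), cluster naming by mean
SN score, and four-way trajectory classification of genes across the
SN-Low -> SN-Mid -> SN-High2 progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import FeatureGeneSets

K2_LABELS = ("SN-High", "SN-Low")
K3_LABELS = ("SN-High2", "SN-Mid", "SN-Low")
TRAJECTORY_CALL_CLASSES = ("up-up", "up-dn", "dn-up", "dn-dn", "unclassified")


@dataclass
class StageAssignment:
    """Per-sample embedding, SN score and named cluster."""

    pc_coordinates: pd.DataFrame  # samples x components
    sn_score: pd.Series
    cluster_label: pd.Series  # SN-High(2)/SN-Mid/SN-Low


def sn_score(
    norm_counts: pd.DataFrame, sets: FeatureGeneSets, statistic: str = "mean"
) -> pd.Series:
    """Per-sample mean (or sum) of normalized counts over SN-featured genes."""
    present = [g for g in norm_counts.index if g in sets.sn_featured]
    if not present:
        raise ValueError("no SN-featured genes present in the matrix")
    sub = norm_counts.loc[present]
    if statistic == "mean":
        return sub.mean(axis=0)
    if statistic == "sum":
        return sub.sum(axis=0)
    raise ValueError(f"unknown statistic {statistic!r}")


def pca_embed(
    norm_counts: pd.DataFrame, feature_set, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(normalized count + 1) over a gene feature set.

    Genes are centered; components come from the SVD of the samples x genes
    matrix.  Sign convention: the largest-|loading| entry of each component
    is made positive, so embeddings are deterministic.

    Returns (coordinates samples x PCs, loadings genes x PCs, explained
    variance fractions).
    """
    feature_set = set(feature_set)
    present = [g for g in norm_counts.index if g in feature_set]
    if len(present) < 2:
        raise ValueError(f"need >= 2 usable feature genes, got {len(present)}")
    if norm_counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = np.log2(norm_counts.loc[present].to_numpy(dtype=float).T + 1.0)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            coords[:, c] *= -1.0
    total = (s**2).sum()
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    pcs = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=norm_counts.columns, columns=pcs),
        pd.DataFrame(loadings, index=present, columns=pcs),
        evr,
    )


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int = 300) -> tuple:
    """One Lloyd run; WCSS is checked to be non-increasing across iterations."""
    prev_wcss = np.inf
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        wcss = d2[np.arange(len(x)), labels].sum()
        if wcss > prev_wcss + 1e-9 * max(prev_wcss, 1.0):
            raise AssertionError("k-means WCSS increased across an iteration")
        new_centers = centers.copy()
        for c in range(len(centers)):
            members = x[labels == c]
            if len(members):
                new_centers[c] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                new_centers[c] = x[d2[np.arange(len(x)), labels].argmax()]
        if np.allclose(new_centers, centers) and wcss >= prev_wcss - 1e-12:
            return labels, wcss
        if abs(prev_wcss - wcss) <= 1e-12 * max(wcss, 1.0):
            centers = new_centers
            prev_wcss = wcss
            break
        centers = new_centers
        prev_wcss = wcss
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return labels, d2[np.arange(len(x)), labels].sum()


def kmeans_cluster(
    coords: pd.DataFrame, k: int, n_init: int = 25, seed: int = 0
) -> pd.Series:
    """Best-of-``n_init`` Lloyd k-means on the embedding coordinates.

    Each run draws its initial centers uniformly without replacement from
    the data points, with run seeds derived from the master seed by counter;
    the labeling with minimal within-cluster sum of squares wins.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    best_labels, best_wcss = None, np.inf
    for run in range(n_init):
        rng = np.random.default_rng([int(seed), run])
        idx = rng.choice(n, size=k, replace=False)
        labels, wcss = _lloyd(x, x[idx].copy())
        if wcss < best_wcss - 1e-12 or best_labels is None:
            best_labels, best_wcss = labels, wcss
    index = coords.index if isinstance(coords, pd.DataFrame) else pd.RangeIndex(n)
    return pd.Series(best_labels, index=index)


def label_clusters(
    labels: pd.Series, scores: pd.Series, k: int
) -> pd.Series:
    """Name clusters by descending mean SN score.

    k=2 -> SN-High / SN-Low; k=3 -> SN-High2 / SN-Mid / SN-Low.  Ties in
    mean score break deterministically by cluster index (with a warning).
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    names = K2_LABELS if k == 2 else K3_LABELS
    means = scores.groupby(labels).mean()
    if means.duplicated().any():
        warnings.warn("tied cluster mean SN scores; breaking ties by cluster index")
    order = means.sort_values(ascending=False, kind="stable").index
    mapping = {cluster: names[rank] for rank, cluster in enumerate(order)}
    return labels.map(mapping)


def stage_samples(
    norm_counts: pd.DataFrame,
    sets: FeatureGeneSets,
    k: int = 2,
    seed: int = 0,
    n_init: int = 25,
) -> StageAssignment:
    """PCA embed, cluster and name in one step."""
    coords, _, _ = pca_embed(norm_counts, sets.sn_featured)
    scores = sn_score(norm_counts, sets)
    labels = kmeans_cluster(coords, k, n_init=n_init, seed=seed)
    return StageAssignment(coords, scores, label_clusters(labels, scores, k))


def trajectory_analysis(
    cm_genes,
    sf,
    assignment: StageAssignment,
    alpha: float = 0.01,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Phase-wise DE across a k=3 staging and the four-way classification.

    Runs SN-Mid vs SN-Low and SN-High2 vs SN-Mid on the gene count matrix
    with the given size factors, then classifies genes by their sign pattern.
    Returns (calls, de_mid_vs_low, de_high_vs_mid).
    """
    from .de import nb_wald_test
    from .normalize import SizeFactors

    labels = assignment.cluster_label
    results = []
    for lo, hi in (("SN-Low", "SN-Mid"), ("SN-Mid", "SN-High2")):
        cols = [c for c in cm_genes.sample_ids if labels[c] in (lo, hi)]
        sub = cm_genes.subset_samples(cols)
        sub_sf = SizeFactors(sf.factors[cols], sf.method, sf.control_set)
        results.append(
            nb_wald_test(sub, sub_sf, labels[cols], levels=(lo, hi))
        )
    de1, de2 = results
    return classify_trajectories(de1, de2, alpha=alpha), de1, de2


def classify_trajectories(
    de_mid_vs_low: pd.DataFrame,
    de_high_vs_mid: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.Series:
    """Four-way gene classification across the staged progression.

    Genes significant (padj < alpha) in at least one of the two phase
    comparisons are classed by the sign pair of their fold changes:
    (+,+) up-up, (+,-) up-dn, (-,+) dn-up, (-,-) dn-dn; the rest are
    'unclassified'.
    """
    if set(de_mid_vs_low.index) != set(de_high_vs_mid.index):
        raise ValueError("the two DE results must cover the same gene universe")
    de2 = de_high_vs_mid.reindex(de_mid_vs_low.index)
    sig = (de_mid_vs_low["padj"] < alpha) | (de2["padj"] < alpha)
    first_up = de_mid_vs_low["lfc"] >= 0
    second_up = de2["lfc"] >= 0
    calls = np.where(
        ~sig,
        "unclassified",
        np.where(
            first_up,
            np.where(second_up, "up-up", "up-dn"),
            np.where(second_up, "dn-up", "dn-dn"),
        ),
    )
    return pd.Series(calls, index=de_mid_vs_low.index)
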