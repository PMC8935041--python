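"""Two-group negative-binomial differential abundance test.

A transparent NB Wald test: per-gene dispersion by method of moments on
normalized counts pooled within groups, log2 fold change of group means
(half-minimum pseudocount when a group mean is zero), a delta-method
standard error, two-sided normal p-values and Benjamini-Hochberg adjustment.
No dispersion shrinkage or independent filtering is applied; recovery of
simulated effects, not equivalence with any particular DE tool, is the
design goal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix
from .normalize import SizeFactors, normalize_counts

LN2 = np.log(2.0)

#: Significance threshold used throughout the analyses.
PADJ_SIGNIFICANT = 0.01


def _split_groups(
    sample_ids, groups: pd.Series, levels: tuple | None = None
) -> tuple[list, list]:
    groups = pd.Series(groups)
    observed = list(pd.unique(groups))
    if len(observed) != 2:
        raise ValueError(f"need exactly two group levels, got {observed}")
    if levels is None:
        levels = observed  # order of appearance
    elif sorted(levels) != sorted(observed):
        raise ValueError(f"levels {levels} do not match observed {observed}")
    g1 = [s for s in sample_ids if groups.get(s) == levels[0]]
    g2 = [s for s in sample_ids if groups.get(s) == levels[1]]
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    return g1, g2


def estimate_dispersion(
    cm: CountMatrix,
    sf: SizeFactors,
    groups: pd.Series,
    levels: tuple | None = None,
) -> pd.Series:
    """Per-gene method-of-moments dispersion on normalized counts.

    Within each group the sample mean and variance of normalized counts are
    computed; these are pooled across groups (degrees-of-freedom weighted)
    and alpha_i = max(0, (var - mean) / mean^2).  Genes with zero pooled mean
    get alpha = 0.
    """
    g1, g2 = _split_groups(cm.sample_ids, groups, levels)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples to estimate dispersion")
    q = normalize_counts(cm, sf)
    means, variances, weights = [], [], []
    for g in (g1, g2):
        sub = q[g].to_numpy()
        means.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1))
        weights.append(len(g) - 1)
    w = np.asarray(weights, dtype=float)
    pooled_mean = (w[0] * means[0] + w[1] * means[1]) / w.sum()
    pooled_var = (w[0] * variances[0] + w[1] * variances[1]) / w.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(pooled_mean > 0, np.maximum(alpha, 0.0), 0.0)
    return pd.Series(alpha, index=cm.feature_ids)


def nb_wald_test(
    cm: CountMatrix,
    sf: SizeFactors,
    groups: pd.Series,
    alpha_i: pd.Series | None = None,
    levels: tuple | None = None,
) -> pd.DataFrame:
    """Wald test of group2 vs group1 on NB means.

    ``levels`` fixes (group1, group2); by default groups are taken in order
    of appearance.  Returns a DataFrame indexed by feature with columns
    ``lfc`` (log2 fold change, group2 over group1), ``se``, ``p`` and
    ``padj`` (BH).
    """
    g1, g2 = _split_groups(cm.sample_ids, groups, levels)
    if alpha_i is None:
        alpha_i = estimate_dispersion(cm, sf, groups, levels)
    alpha = alpha_i.reindex(cm.feature_ids).fillna(0.0).to_numpy()
    q = normalize_counts(cm, sf)
    m1 = q[g1].to_numpy().mean(axis=1)
    m2 = q[g2].to_numpy().mean(axis=1)
    positive = q.to_numpy()[q.to_numpy() > 0]
    pseudo = 0.5 * positive.min() if positive.size else 0.5
    m1p = np.where(m1 > 0, m1, pseudo)
    m2p = np.where(m2 > 0, m2, pseudo)
    lfc = np.log2(m2p / m1p)
    var_log2 = (1.0 / LN2**2) * (
        (1.0 / m1p + alpha) / len(g1) + (1.0 / m2p + alpha) / len(g2)
    )
    se = np.sqrt(var_log2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    result = pd.DataFrame(
        {"lfc": lfc, "se": se, "p": p, "padj": bh_adjust(p)}, index=cm.feature_ids
    )
    return result


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    padj_(k) = min_{r >= k} p_(r) * n / r over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out
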