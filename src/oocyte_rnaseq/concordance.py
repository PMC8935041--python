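"""Reproducibility analysis across libraries and datasets.

Pairwise Pearson correlations of log-scale normalized expression at the
library and dataset level, and Euclidean sample distance matrices -- the
readouts behind the single-vs-bulk reproducibility comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import CountMatrix
from .normalize import dataset_profile, total_count_normalize


def pairwise_library_correlation(
    cm: CountMatrix,
    min_reads: int = 5,
    pseudocount: float = 1.0,
    gene_subset=None,
) -> pd.DataFrame:
    """Library x library Pearson r of log10 normalized counts.

    For each pair, genes with at least ``min_reads`` raw reads in both
    libraries are used; counts are total-count normalized (per mille of the
    library) before log10(x + pseudocount).  ``gene_subset`` optionally
    restricts to e.g. coding genes.
    """
    values = cm.values
    if gene_subset is not None:
        values = values.loc[[g for g in values.index if g in set(gene_subset)]]
    if values.empty:
        raise ValueError("empty gene universe for library correlation")
    sub = CountMatrix(values, cm.feature_class.loc[values.index])
    norm = total_count_normalize(sub) * 1e6
    samples = list(values.columns)
    n = len(samples)
    out = np.eye(n)
    raw = values.to_numpy()
    logn = np.log10(norm.to_numpy() + pseudocount)
    for a in range(n):
        for b in range(a + 1, n):
            valid = (raw[:, a] >= min_reads) & (raw[:, b] >= min_reads)
            if valid.sum() < 3:
                raise ValueError(
                    f"fewer than 3 shared valid genes between "
                    f"{samples[a]!r} and {samples[b]!r}"
                )
            r = np.corrcoef(logn[valid, a], logn[valid, b])[0, 1]
            out[a, b] = out[b, a] = r
    return pd.DataFrame(out, index=samples, columns=samples)


def pairwise_dataset_correlation(
    cm: CountMatrix, meta: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Dataset x dataset Pearson r of log10 mean expression profiles.

    Per dataset, gene counts are averaged across its libraries and divided
    by the mean of the averaged counts; correlations are computed on
    log10(x + pseudocount) over the shared gene universe.
    """
    groups = meta.groupby("dataset")["sample_id"].apply(list)
    if groups.empty:
        raise ValueError("no datasets in metadata")
    profiles = pd.DataFrame(
        {ds: dataset_profile(cm.subset_samples(samps)) for ds, samps in groups.items()}
    )
    logp = np.log10(profiles.to_numpy() + pseudocount)
    datasets = list(profiles.columns)
    n = len(datasets)
    out = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            r = np.corrcoef(logp[:, a], logp[:, b])[0, 1]
            out[a, b] = out[b, a] = r
    return pd.DataFrame(out, index=datasets, columns=datasets)


def sample_distance_matrix(norm_counts: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between samples on log2(normalized count + 1)."""
    if norm_counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = np.log2(norm_counts.to_numpy(dtype=float).T + 1.0)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(d, index=norm_counts.columns, columns=norm_counts.columns)
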