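"""UMI-aware and coordinate-only read deduplication.

Exact-match keys only: the UMI scheme keeps one read per
(sample, position, strand, UMI) key, the coordinate scheme one per
(sample, position, strand).  The coordinate key is strictly coarser, so it
can only remove more reads.  ``dedup_concordance`` quantifies how little the
downstream analysis changes when duplicates are collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix
from .normalize import size_factors_median_ratio, total_count_normalize
from .de import nb_wald_test
from .synthetic import ReadRecord


def umi_capacity(length: int) -> int:
    """Number of distinct UMIs of the given length over {A, C, G, T}."""
    if length < 1:
        raise ValueError("UMI length must be >= 1")
    return 4**length


def _dedup_by_key(reads: list[ReadRecord], keyfunc) -> list[ReadRecord]:
    seen = set()
    kept = []
    for read in reads:
        key = keyfunc(read)
        if key not in seen:
            seen.add(key)
            kept.append(read)
    return kept


def dedup_umi(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Keep the first read per (sample, position, strand, UMI); stable order."""
    return _dedup_by_key(
        reads, lambda r: (r.sample_id, r.position, r.strand, r.umi)
    )


def dedup_coordinate(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Keep the first read per (sample, position, strand), ignoring UMIs."""
    return _dedup_by_key(reads, lambda r: (r.sample_id, r.position, r.strand))


@dataclass
class ConcordanceReport:
    """Original-vs-deduplicated concordance summary."""

    retained_fraction: pd.Series  # per sample
    mean_count_r: float  # Pearson r of log10 normalized gene means
    lfc_r: float  # Pearson r of the two MII-vs-GV lfc vectors


def dedup_concordance(
    original: CountMatrix, deduped: CountMatrix, meta: pd.DataFrame
) -> ConcordanceReport:
    """Compare a count matrix before and after deduplication.

    Reports the retained read fraction per sample, the gene-wise Pearson r of
    log10 total-count-normalized mean counts, and the Pearson r between the
    MII-vs-GV log2 fold change vectors computed on each matrix.
    """
    if list(original.feature_ids) != list(deduped.feature_ids) or list(
        original.sample_ids
    ) != list(deduped.sample_ids):
        raise ValueError("original and deduped matrices must share genes and samples")
    retained = deduped.values.sum(axis=0) / original.values.sum(axis=0)

    mean_o = total_count_normalize(original).mean(axis=1)
    mean_d = total_count_normalize(deduped).mean(axis=1)
    keep = (mean_o > 0) & (mean_d > 0)
    mean_r, _ = stats.pearsonr(
        np.log10(mean_o[keep]), np.log10(mean_d[keep])
    )

    groups = pd.Series(meta["stage"].to_numpy(), index=meta["sample_id"])
    de_o = nb_wald_test(original, size_factors_median_ratio(original), groups)
    de_d = nb_wald_test(deduped, size_factors_median_ratio(deduped), groups)
    lfc_r, _ = stats.pearsonr(de_o["lfc"], de_d["lfc"])
    return ConcordanceReport(retained, float(mean_r), float(lfc_r))


def reads_to_frame(reads: list[ReadRecord]) -> pd.DataFrame:
    """Tabulate read records (sample_id, gene_id, position, strand, umi)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reads],
            "gene_id": [r.gene_id for r in reads],
            "position": [r.position for r in reads],
            "strand": [r.strand for r in reads],
            "umi": [r.umi for r in reads],
        }
    )


def frame_to_reads(df: pd.DataFrame) -> list[ReadRecord]:
    return [
        ReadRecord(
            sample_id=str(row.sample_id),
            gene_id=str(row.gene_id),
            position=int(row.position),
            strand=str(row.strand),
            umi=str(row.umi),
        )
        for row in df.itertuples(index=False)
    ]
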