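"""Gene filtering and size-factor normalization.

The workhorse is the median-of-ratios size factor: each sample's factor is
the median, over reference features, of its counts divided by the feature's
geometric mean across samples.  When the transcriptome itself shrinks (GV ->
MII degradation, fractional oocytes) the all-gene median absorbs the global
shift, so spike-ins (ERCC) or maturation-stable genes (constGenes) are passed
as the control set to anchor the factors to absolute RNA content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CountMatrix

#: Libraries used for spike-based analyses need at least this many spike reads.
MIN_SPIKE_READS = 500


@dataclass
class SizeFactors:
    """Per-sample positive scalings s_j."""

    factors: pd.Series
    method: str  # 'median_ratio' or 'control_genes'
    control_set: frozenset | None = None

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("size factors must be positive and finite")

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


def filter_valid_features(
    cm: CountMatrix, min_reads: int = 5, min_libraries: int = 2
) -> CountMatrix:
    """Keep features with >= ``min_reads`` reads in >= ``min_libraries`` libraries.

    Row order is preserved; the operation is idempotent.
    """
    keep = (cm.values >= min_reads).sum(axis=1) >= min_libraries
    return CountMatrix(cm.values.loc[keep], cm.feature_class.loc[keep])


def size_factors_median_ratio(
    cm: CountMatrix, control_set=None
) -> SizeFactors:
    """Median-of-ratios size factors, optionally restricted to control features.

    The reference r_i is the geometric mean of counts across samples, computed
    only over features positive in every sample (and in ``control_set`` when
    given); s_j is the median over those features of k_ij / r_i.  Even-sized
    medians average the middle two values.
    """
    values = cm.values
    if control_set is not None:
        control_set = set(control_set)
        present = [f for f in values.index if f in control_set]
        values = values.loc[present]
    arr = values.to_numpy(dtype=float)
    usable = np.all(arr > 0, axis=1)
    if control_set is not None and usable.sum() < 2:
        raise ValueError(
            "need at least 2 control features with all-positive counts; "
            f"got {int(usable.sum())}"
        )
    if not usable.any():
        raise ValueError("no usable reference features (none positive in all samples)")
    pos = arr[usable]
    log_ref = np.mean(np.log(pos), axis=1)
    ratios = pos / np.exp(log_ref)[:, None]
    factors = pd.Series(np.median(ratios, axis=0), index=cm.sample_ids)
    method = "control_genes" if control_set is not None else "median_ratio"
    return SizeFactors(
        factors, method, frozenset(control_set) if control_set else None
    )


def normalize_counts(cm: CountMatrix, sf: SizeFactors) -> pd.DataFrame:
    """Normalized counts q_ij = k_ij / s_j."""
    missing = [s for s in cm.sample_ids if s not in sf.factors.index]
    if missing:
        raise ValueError(f"size factors missing for samples: {missing[:5]}")
    return cm.values / sf.factors[cm.sample_ids]


def total_count_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Divide each column by its total; columns sum to 1."""
    totals = cm.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero total count in samples: {zero[:5]}")
    return cm.values / totals


def dataset_profile(cm: CountMatrix) -> pd.Series:
    """Average gene counts across a dataset's libraries, then divide by the
    mean of the averaged gene counts (one scalar per dataset)."""
    avg = cm.values.mean(axis=1)
    return avg / avg.mean()


def spike_read_totals(cm: CountMatrix) -> pd.Series:
    """Total spike-in reads per library."""
    return cm.values.loc[cm.feature_class == "spike"].sum(axis=0)


def filter_spike_sufficient(
    cm: CountMatrix, min_spike_reads: int = MIN_SPIKE_READS
) -> CountMatrix:
    """Drop libraries with fewer than ``min_spike_reads`` spike reads."""
    keep = spike_read_totals(cm) >= min_spike_reads
    return cm.subset_samples(cm.sample_ids[keep])
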