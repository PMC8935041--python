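"""rRNA 5'-ETS scoring.

Residual rRNA coverage over the 13,403-base primary transcript is
normalized to unit mass per library; the 5'-ETS score is the normalized
mass inside transcript positions 500-1,500 (inclusive), a window chosen to
dodge non-specific coverage spikes elsewhere in the 5'-ETS.  Libraries are
split into 5'-ETS-High and -Low around the mean score (or an explicit
threshold), and the score is correlated against the staging PC1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import RRNA_TRANSCRIPT_LENGTH

DEFAULT_ETS_WINDOW = (500, 1_500)


def normalize_coverage(coverage: np.ndarray) -> np.ndarray:
    """Divide per-base coverage by the total over the whole transcript."""
    cov = np.asarray(coverage, dtype=float)
    if cov.ndim != 1 or len(cov) != RRNA_TRANSCRIPT_LENGTH:
        raise ValueError(
            f"coverage must have exactly {RRNA_TRANSCRIPT_LENGTH} positions, "
            f"got {cov.shape}"
        )
    if np.any(cov < 0):
        raise ValueError("coverage values must be non-negative")
    total = cov.sum()
    if total <= 0:
        raise ValueError("no rRNA signal (all-zero coverage profile)")
    return cov / total


def ets_score(
    normalized: np.ndarray, window: tuple[int, int] = DEFAULT_ETS_WINDOW
) -> float:
    """Sum of normalized coverage over an inclusive 1-based position window."""
    lo, hi = window
    n = len(normalized)
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"window {window} outside positions 1..{n}")
    return float(np.sum(normalized[lo - 1 : hi]))


def score_profiles(
    profiles: dict[str, np.ndarray], window: tuple[int, int] = DEFAULT_ETS_WINDOW
) -> pd.Series:
    """Normalize and score a set of per-sample coverage profiles."""
    return pd.Series(
        {s: ets_score(normalize_coverage(c), window) for s, c in profiles.items()}
    )


def assign_ets_groups(
    scores: pd.Series, threshold: float | None = None
) -> pd.DataFrame:
    """Split samples into 5'-ETS High/Low around a threshold.

    The threshold defaults to the mean score over all samples; scores
    strictly above it are High, ties and below are Low.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to assign 5'-ETS groups")
    if threshold is None:
        threshold = float(scores.mean())
    group = np.where(scores > threshold, "High", "Low")
    if (group == group[0]).all():
        warnings.warn("all samples fall on one side of the 5'-ETS threshold")
    return pd.DataFrame(
        {"score": scores, "group": group, "threshold": threshold},
        index=scores.index,
    )


def correlate_pc1_ets(pc1: pd.Series, scores: pd.Series) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between PC1 and the 5'-ETS score."""
    shared = [s for s in pc1.index if s in scores.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 paired samples")
    x = pc1[shared].to_numpy(dtype=float)
    y = scores[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in PC1 or 5'-ETS scores")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
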