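"""Maturation-stable gene (constGene) selection and normalization comparison.

constGenes are genes whose transcript abundance changes less than 50% from
GV to MII in both a poly(A) and a RiboMinus comparison (each run with
spike-anchored size factors).  They substitute for ERCC spike-ins as
normalization controls when no spikes were added to a library.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import CountMatrix
from .de import nb_wald_test
from .normalize import SizeFactors, size_factors_median_ratio


def select_const_genes(
    de_polyA: pd.DataFrame,
    de_riboM: pd.DataFrame,
    max_fold: float = 1.5,
    expression_filter=None,
    symmetric: bool = True,
) -> frozenset:
    """Genes with |log2 FC| < log2(max_fold) in BOTH library-type comparisons.

    ``symmetric=True`` reads "less than 50% change" in log space (ratio in
    (1/max_fold, max_fold)); ``symmetric=False`` uses the asymmetric band
    (2 - max_fold, max_fold) on the ratio scale.  ``expression_filter``
    optionally restricts candidates to an expressed-gene universe.
    """
    shared = de_polyA.index.intersection(de_riboM.index)
    if shared.empty:
        raise ValueError("the two DE results share no genes")
    lfc_a = de_polyA.loc[shared, "lfc"]
    lfc_b = de_riboM.loc[shared, "lfc"]
    if symmetric:
        bound = np.log2(max_fold)
        stable = (lfc_a.abs() < bound) & (lfc_b.abs() < bound)
    else:
        lo, hi = np.log2(2.0 - max_fold), np.log2(max_fold)
        stable = lfc_a.between(lo, hi, inclusive="neither") & lfc_b.between(
            lo, hi, inclusive="neither"
        )
    selected = set(shared[stable])
    if expression_filter is not None:
        selected &= set(expression_filter)
    return frozenset(selected)


def compare_normalizations(
    cm: CountMatrix,
    meta: pd.DataFrame,
    ercc_set,
    const_set,
    group_col: str = "stage",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the two-group DE test under three size-factor methods.

    Returns (per-gene lfc table with columns median_ratio/ercc/constgenes,
    distribution summary with median and quartiles per method).  Only gene
    rows are tested; spikes and controls serve in the factors.
    """
    ercc_set, const_set = set(ercc_set), set(const_set)
    for name, ctrl in (("ercc", ercc_set), ("constgenes", const_set)):
        if not (ctrl & set(cm.feature_ids)):
            raise ValueError(f"{name} control set absent from the matrix")
    groups = pd.Series(meta[group_col].to_numpy(), index=meta["sample_id"])
    factors: dict[str, SizeFactors] = {
        "median_ratio": size_factors_median_ratio(cm.genes_only()),
        "ercc": size_factors_median_ratio(cm, control_set=ercc_set),
        "constgenes": size_factors_median_ratio(cm, control_set=const_set),
    }
    genes = cm.genes_only()
    lfc = {}
    for method, sf in factors.items():
        lfc[method] = nb_wald_test(genes, sf, groups)["lfc"]
    table = pd.DataFrame(lfc)
    summary = table.describe(percentiles=[0.25, 0.5, 0.75]).loc[
        ["25%", "50%", "75%"]
    ]
    summary.index = ["q1", "median", "q3"]
    return table, summary
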