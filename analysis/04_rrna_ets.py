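#!/usr/bin/env python
"""rRNA 5'-ETS scoring of the staged oocytes.

Reads the per-oocyte rRNA coverage tracks (bedGraph) written by
01_simulate_cohort.py, normalizes each to unit mass over the 13,403-base
primary transcript, sums the 500-1,500 window to get the 5'-ETS score,
splits High/Low around the mean score, correlates the score with the
SN-staging PC1, and contrasts SN-featured genes in High vs Low.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import oocyte_rnaseq as oq


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cov_dir = args.cohort / "coverage"
    profiles = {
        p.stem: oq.read_coverage_bedgraph(p)
        for p in sorted(cov_dir.glob("*.bedgraph"))
    }
    scores = oq.score_profiles(profiles)
    groups = oq.assign_ets_groups(scores)
    groups.index.name = "sample_id"
    groups.to_csv(args.out / "ets_scores.tsv", sep="\t")

    cm = oq.read_count_matrix(args.cohort / "staging_counts.tsv")
    cm = oq.filter_valid_features(cm)
    sn = frozenset(oq.read_gene_list(args.cohort / "sn_featured.txt"))
    sf = oq.size_factors_median_ratio(cm.genes_only())
    q = oq.normalize_counts(cm.genes_only(), sf)
    coords, _, evr = oq.pca_embed(q, sn)
    r, p = oq.correlate_pc1_ets(coords["PC1"], scores)

    labels = pd.Series(groups["group"].to_numpy(), index=groups.index)
    de = oq.nb_wald_test(cm.genes_only(), sf, labels, levels=("Low", "High"))
    sn_lfc = de.loc[[g for g in sn if g in de.index], "lfc"]

    print(
        f"5'-ETS scores: mean {scores.mean():.5f} (High/Low threshold), "
        f"{(groups['group'] == 'High').sum()} High / "
        f"{(groups['group'] == 'Low').sum()} Low oocytes"
    )
    print(f"PC1 vs 5'-ETS score: Pearson r = {r:.3f} (p = {p:.2e})")
    print(
        f"SN-featured genes in 5'-ETS-High vs -Low: mean lfc = "
        f"{sn_lfc.mean():+.3f} ({(sn_lfc > 0).mean():.0%} positive)"
    )
    print(
        "Residual 5'-ETS level in poly(A) libraries tracks the SN-ward "
        "staging axis, supporting 5'-ETS as an SN-phase marker."
    )


if __name__ == "__main__":
    main()
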