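#!/usr/bin/env python
"""Select maturation-stable genes (constGenes) and validate them as
normalization controls.

Runs GV-vs-MII differential tests on two simulated library types (poly(A)
and RiboMinus) with spike-anchored size factors, keeps genes changing less
than 50% in both, scores the selection against the generator's truth-stable
genes, and shows that constGene-anchored fold changes reproduce the
ERCC-anchored ones.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import oocyte_rnaseq as oq
from oocyte_rnaseq.synthetic import SimConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(
        n_gv=10,
        n_mii=10,
        dispersion=0.01,
        mu_log_mean=5.5,
        mu_log_sd=0.6,
        n_sn_featured=0,
        n_nsn_featured=0,
        trajectory_fractions={},
    )
    truth = oq.simulate_truth(cfg, seed=args.seed)
    des, cms, metas = {}, {}, {}
    for i, lt in enumerate(["polyA", "riboMinus"]):
        cm, meta = oq.simulate_counts(
            truth, seed=args.seed + 10 + i, library_type=lt
        )
        cm = oq.filter_valid_features(cm)
        sf = oq.size_factors_median_ratio(cm, control_set=cm.spike_ids())
        groups = pd.Series(meta["stage"].to_numpy(), index=meta["sample_id"])
        des[lt] = oq.nb_wald_test(cm.genes_only(), sf, groups, levels=("GV", "MII"))
        cms[lt], metas[lt] = cm, meta

    selected = oq.select_const_genes(des["polyA"], des["riboMinus"])
    oq.write_gene_list(sorted(selected), args.out / "constgenes.txt")
    flat = set(truth.flat_genes)
    tp = len(selected & flat)
    print(
        f"selected {len(selected)} constGenes "
        f"(|lfc| < log2(1.5) in both library types); "
        f"sensitivity {tp / len(flat):.3f}, precision {tp / len(selected):.3f} "
        f"against {len(flat)} truth-stable genes"
    )

    table, summary = oq.compare_normalizations(
        cms["polyA"], metas["polyA"], ercc_set=cms["polyA"].spike_ids(),
        const_set=selected,
    )
    summary.to_csv(args.out / "normalization_comparison.tsv", sep="\t")
    r = np.corrcoef(table["ercc"], table["constgenes"])[0, 1]
    print("\nMII-vs-GV lfc distribution by size-factor method:")
    print(summary.round(3).to_string())
    print(
        f"\nconstGene vs ERCC per-gene lfc: Pearson r = {r:.4f}; the "
        "all-gene median-ratio medians sit near 0 because library-internal "
        "factors absorb the global degradation the spike-anchored factors "
        "reveal."
    )


if __name__ == "__main__":
    main()
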