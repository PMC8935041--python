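#!/usr/bin/env python
"""Fractional-oocyte dilution series: spike-anchored vs all-gene
normalization.

Simulates 1, 1/2, 1/4 and 1/8 oocyte-equivalent libraries (spikes added
after dilution, so their expectations do not scale), then contrasts the
per-gene log2 fold changes of each fraction against the whole oocyte under
(a) ERCC-anchored size factors and (b) all-gene median-of-ratios factors.
The spike-anchored readout should track log2(fraction); the all-gene
factors should absorb the dilution entirely.
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

    truth = oq.simulate_truth(SimConfig(dispersion=0.01), seed=args.seed)
    cm, meta = oq.simulate_dilution_series(truth, seed=args.seed + 1)
    cm = oq.filter_valid_features(cm)
    sf_ercc = oq.size_factors_median_ratio(cm, control_set=cm.spike_ids())
    sf_gene = oq.size_factors_median_ratio(cm.genes_only())
    genes = cm.genes_only()
    frac_of = meta.set_index("sample_id")["fraction"]

    rows = []
    for f in (0.5, 0.25, 0.125):
        cols = meta.loc[meta.fraction.isin([1.0, f]), "sample_id"].tolist()
        grp = pd.Series(
            np.where(frac_of[cols] == 1.0, "one", "frac"), index=cols
        )
        sub = genes.subset_samples(cols)
        for method, sf in (("ercc", sf_ercc), ("median_ratio", sf_gene)):
            de = oq.nb_wald_test(
                sub,
                oq.SizeFactors(sf.factors[cols], sf.method),
                grp,
                levels=("one", "frac"),
            )
            rows.append(
                {
                    "fraction": f,
                    "method": method,
                    "expected_lfc": np.log2(f) if method == "ercc" else 0.0,
                    "median_lfc": de["lfc"].median(),
                    "q1_lfc": de["lfc"].quantile(0.25),
                    "q3_lfc": de["lfc"].quantile(0.75),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "dilution_lfc_summary.tsv", sep="\t", index=False)
    print(table.round(3).to_string(index=False))
    print(
        "\nERCC-anchored medians track log2(fraction); all-gene median-of-"
        "ratios factors absorb the dilution (medians near 0), reproducing "
        "why library-internal normalization cannot see transcriptome loss."
    )


if __name__ == "__main__":
    main()
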