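#!/usr/bin/env python
"""Simulate the synthetic single-oocyte cohorts used by the downstream
analyses and write them to results/cohort/ as plain TSV.

Two cohorts are produced:

* staging cohort -- 78 GV oocytes spanning a latent NSN->SN progression,
  with SN-/NSN-featured gene lists and ground-truth sidecars;
* maturation cohort -- 10 GV vs 10 MII oocytes with ERCC spike-ins and a
  global 75% loss of transcriptome mass.
"""

import argparse
from pathlib import Path

import pandas as pd

import oocyte_rnaseq as oq
from oocyte_rnaseq.synthetic import SimConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    staging_cfg = SimConfig(n_gv=78, n_mii=0, dispersion=0.05)
    truth = oq.simulate_truth(staging_cfg, seed=args.seed)
    cm, meta = oq.simulate_counts(truth, dataset="staging")
    oq.write_count_matrix(cm, out / "staging_counts.tsv")
    oq.write_sample_meta(meta, out / "staging_meta.tsv")
    oq.write_gene_list(truth.sn_featured, out / "sn_featured.txt")
    oq.write_gene_list(truth.nsn_featured, out / "nsn_featured.txt")
    oq.write_spike_table(truth.spike_concentration, out / "spike_table.tsv")
    truth.stage_score.rename("stage_score").to_csv(
        out / "staging_truth_t.tsv", sep="\t"
    )
    truth.trajectory_class.rename("trajectory_class").to_csv(
        out / "staging_truth_trajectory.tsv", sep="\t"
    )
    profiles = oq.simulate_coverage(truth)
    cov_dir = out / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for sample, cov in profiles.items():
        oq.write_coverage_bedgraph(cov, cov_dir / f"{sample}.bedgraph")
    print(
        f"staging cohort: {cm.values.shape[0]} features x "
        f"{cm.values.shape[1]} GV oocytes; "
        f"{len(truth.sn_featured)} SN-featured genes; "
        f"coverage tracks for {len(profiles)} oocytes"
    )

    mat_cfg = SimConfig(
        n_gv=10,
        n_mii=10,
        dispersion=0.02,
        mu_log_mean=6.5,
        n_sn_featured=0,
        n_nsn_featured=0,
        trajectory_fractions={},
    )
    mat_truth = oq.simulate_truth(mat_cfg, seed=args.seed + 1)
    mat_cm, mat_meta = oq.simulate_counts(mat_truth, dataset="maturation")
    oq.write_count_matrix(mat_cm, out / "maturation_counts.tsv")
    oq.write_sample_meta(mat_meta, out / "maturation_meta.tsv")
    oq.write_gene_list(mat_truth.flat_genes, out / "maturation_truth_flat.txt")
    retained = (
        (mat_truth.retention * mat_truth.mu).sum() / mat_truth.mu.sum()
    )
    print(
        f"maturation cohort: {mat_cm.values.shape[1]} libraries, "
        f"global retained transcriptome mass {retained:.2f} "
        f"({len(mat_truth.flat_genes)} truth-stable genes)"
    )


if __name__ == "__main__":
    main()
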