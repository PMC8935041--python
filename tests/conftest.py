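import numpy as np
import pandas as pd
import pytest

import oocyte_rnaseq as oq
from oocyte_rnaseq.core_io import CountMatrix, FeatureGeneSets
from oocyte_rnaseq.synthetic import SimConfig


@pytest.fixture
def tiny_cm():
    """3 genes x 2 samples with known column sums (9, 12)."""
    values = pd.DataFrame(
        [[1, 2], [3, 4], [5, 6]],
        index=["geneA", "geneB", "geneC"],
        columns=["s1", "s2"],
    )
    return CountMatrix(values)


@pytest.fixture(scope="session")
def staged_cohort():
    """78 GV oocytes with a latent NSN->SN progression (the staging cohort).

    Shared across staging and 5'-ETS tests; everything downstream of the
    generator is recomputed per test from these objects.
    """
    cfg = SimConfig(n_gv=78, n_mii=0, dispersion=0.05)
    truth = oq.simulate_truth(cfg, seed=0)
    cm, meta = oq.simulate_counts(truth)
    cm = oq.filter_valid_features(cm)
    sf = oq.size_factors_median_ratio(cm.genes_only())
    q = oq.normalize_counts(cm.genes_only(), sf)
    sets = FeatureGeneSets(
        sn_featured=frozenset(truth.sn_featured),
        nsn_featured=frozenset(truth.nsn_featured),
    )
    return {
        "truth": truth,
        "cm": cm,
        "meta": meta,
        "sf": sf,
        "q": q,
        "sets": sets,
    }


@pytest.fixture(scope="session")
def maturation_cohort():
    """GV vs MII cohort with ERCC spikes, deep libraries, n = 10 per stage."""
    cfg = SimConfig(
        n_gv=10,
        n_mii=10,
        dispersion=0.02,
        mu_log_mean=6.5,
        n_sn_featured=0,
        n_nsn_featured=0,
        trajectory_fractions={},
    )
    truth = oq.simulate_truth(cfg, seed=1)
    cm, meta = oq.simulate_counts(truth, seed=21)
    cm = oq.filter_valid_features(cm)
    return {"truth": truth, "cm": cm, "meta": meta}


def stage_groups(meta):
    return pd.Series(meta["stage"].to_numpy(), index=meta["sample_id"])
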