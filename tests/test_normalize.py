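import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oocyte_rnaseq as oq
from oocyte_rnaseq.core_io import CountMatrix
from oocyte_rnaseq.normalize import (
    SizeFactors,
    dataset_profile,
    filter_spike_sufficient,
    filter_valid_features,
    normalize_counts,
    size_factors_median_ratio,
    total_count_normalize,
)
from oocyte_rnaseq.synthetic import SimConfig


def make_cm(array, samples=None):
    arr = np.asarray(array)
    return CountMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=samples or [f"s{j}" for j in range(arr.shape[1])],
        )
    )


class TestFilterValidFeatures:
    @pytest.mark.parametrize(
        "counts,kept",
        [
            ([5, 5, 0], True),  # boundary: >=5 in exactly 2 libraries
            ([4, 100, 0], False),  # only one library reaches 5
            ([5, 4, 4], False),
            ([6, 6, 6], True),
        ],
    )
    def test_rule_application(self, counts, kept):
        cm = make_cm([counts])
        out = filter_valid_features(cm)
        assert (len(out.feature_ids) == 1) == kept

    def test_all_zero_matrix_empties(self):
        out = filter_valid_features(make_cm(np.zeros((4, 3), dtype=int)))
        assert len(out.feature_ids) == 0

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(0)
        cm = make_cm(rng.integers(0, 20, (50, 4)))
        once = filter_valid_features(cm)
        twice = filter_valid_features(once)
        assert once == twice
        positions = {g: i for i, g in enumerate(cm.feature_ids)}
        kept = [positions[g] for g in once.feature_ids]
        assert kept == sorted(kept)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        cm = make_cm([[10, 10], [3, 3], [7, 7]])
        sf = size_factors_median_ratio(cm)
        np.testing.assert_allclose(sf.factors, 1.0)

    def test_closed_form_two_by_two(self):
        # every ratio k_ij / r_i is 2^(-1/2) or 2^(1/2)
        cm = make_cm([[10, 20], [30, 60]])
        sf = size_factors_median_ratio(cm)
        np.testing.assert_allclose(
            sf.factors, [2**-0.5, 2**0.5], rtol=1e-12
        )

    def test_even_median_averages_middle_two(self):
        # ratios per sample: {1/2, 2} in s1 would tie; use 4 features
        cm = make_cm([[1, 1], [2, 2], [4, 4], [100, 100]])
        sf = size_factors_median_ratio(cm)
        np.testing.assert_allclose(sf.factors, 1.0)

    def test_no_reference_features_error(self):
        cm = make_cm([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="no usable reference"):
            size_factors_median_ratio(cm)

    def test_control_set_restriction(self):
        values = pd.DataFrame(
            {"s1": [10, 100], "s2": [10, 400]},
            index=["ERCC-00001", "geneA"],
        )
        cm = CountMatrix(values)
        sf = size_factors_median_ratio(cm, control_set={"ERCC-00001", "geneA"})
        assert sf.method == "control_genes"
        with pytest.raises(ValueError, match="2 control features"):
            size_factors_median_ratio(cm, control_set={"ERCC-00001"})

    def test_control_factors_ignore_noncontrol_rescale(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(1, 500, (30, 4))
        cm = make_cm(arr)
        controls = [f"g{i}" for i in range(5)]
        sf1 = size_factors_median_ratio(cm, control_set=controls)
        arr2 = arr.copy()
        arr2[5:] *= 17  # rescale non-control rows arbitrarily
        sf2 = size_factors_median_ratio(make_cm(arr2), control_set=controls)
        np.testing.assert_allclose(sf1.factors, sf2.factors, rtol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(1, 50),
        st.integers(0, 4),
    )
    def test_column_scaling_equivariance(self, seed, factor, col):
        """Scaling column j by c scales s_j by exactly c relative to every
        other factor.

        The geometric-mean reference itself shifts by the common c^(1/n), so
        the exact statement is about factor ratios: s_j/s_l gains exactly c,
        and the untouched columns keep their ratios to each other.
        """
        rng = np.random.default_rng(seed)
        arr = rng.integers(1, 300, (20, 5))
        sf = size_factors_median_ratio(make_cm(arr)).factors
        scaled = arr.copy()
        scaled[:, col] *= factor
        sf2 = size_factors_median_ratio(make_cm(scaled)).factors
        others = [j for j in range(5) if j != col]
        for l in others:
            np.testing.assert_allclose(
                sf2.iloc[col] / sf2.iloc[l],
                factor * sf.iloc[col] / sf.iloc[l],
                rtol=1e-9,
            )
        for a in others:
            for b in others:
                np.testing.assert_allclose(
                    sf2.iloc[a] / sf2.iloc[b], sf.iloc[a] / sf.iloc[b], rtol=1e-9
                )

    def test_recovers_true_size_factors(self):
        """Control-gene factors track the simulated truth at r >= 0.99."""
        cfg = SimConfig(
            n_genes=2000, n_gv=6, n_mii=6, n_spikes=92, dispersion=0.0
        )
        truth = oq.simulate_truth(cfg, seed=2)
        cm, _ = oq.simulate_counts(truth, seed=3)
        sf = size_factors_median_ratio(cm, control_set=cm.spike_ids())
        r = np.corrcoef(sf.factors, truth.size_factor[cm.sample_ids])[0, 1]
        assert r >= 0.99

    def test_dilution_spike_factors_flat_gene_factors_scale(self):
        """Spike factors ignore the dilution; all-gene factors track it."""
        cfg = SimConfig(n_genes=1000, dispersion=0.0, mu_log_mean=6.0)
        truth = oq.simulate_truth(cfg, seed=4)
        cm, meta = oq.simulate_dilution_series(
            truth, fractions=(1.0, 0.25), n_replicates=2, seed=5
        )
        sf_spike = size_factors_median_ratio(cm, control_set=cm.spike_ids())
        sf_gene = size_factors_median_ratio(cm.genes_only())
        quarter = meta.loc[meta.fraction == 0.25, "sample_id"].iloc[0]
        full = meta.loc[meta.fraction == 1.0, "sample_id"].iloc[0]
        assert sf_spike.factors[quarter] == pytest.approx(
            sf_spike.factors[full], rel=0.05
        )
        assert sf_gene.factors[full] / sf_gene.factors[quarter] == pytest.approx(
            4.0, rel=0.15
        )


class TestNormalizeCounts:
    def test_unit_factors_identity(self, tiny_cm):
        sf = SizeFactors(pd.Series(1.0, index=["s1", "s2"]), "median_ratio")
        assert normalize_counts(tiny_cm, sf).equals(tiny_cm.values * 1.0)

    def test_doubled_column_normalizes_back(self):
        arr = np.array([[10, 20], [30, 60], [5, 10]])
        cm = make_cm(arr)
        sf = size_factors_median_ratio(cm)
        q = normalize_counts(cm, sf)
        np.testing.assert_allclose(q["s0"], q["s1"], rtol=1e-12)

    def test_missing_sample_error(self, tiny_cm):
        sf = SizeFactors(pd.Series({"s1": 1.0}), "median_ratio")
        with pytest.raises(ValueError, match="missing"):
            normalize_counts(tiny_cm, sf)

    def test_column_ratio_medians_equal_one(self):
        """Definitional check: median over reference features of the
        normalized-to-reference ratio is 1 in every sample."""
        rng = np.random.default_rng(6)
        cm = make_cm(rng.integers(1, 1000, (101, 4)))
        sf = size_factors_median_ratio(cm)
        arr = cm.values.to_numpy(dtype=float)
        ref = np.exp(np.mean(np.log(arr), axis=1))
        ratios = normalize_counts(cm, sf).to_numpy() / ref[:, None]
        np.testing.assert_allclose(np.median(ratios, axis=0), 1.0, rtol=1e-12)


class TestTotalCountNormalize:
    def test_column_fractions(self):
        cm = make_cm([[2], [3], [5]])
        np.testing.assert_allclose(
            total_count_normalize(cm)["s0"], [0.2, 0.3, 0.5]
        )

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(7)
        cm = make_cm(rng.integers(0, 50, (30, 5)) + 1)
        np.testing.assert_allclose(total_count_normalize(cm).sum(axis=0), 1.0)

    def test_zero_column_names_sample(self):
        cm = make_cm([[0, 1], [0, 2]], samples=["empty", "ok"])
        with pytest.raises(ValueError, match="empty"):
            total_count_normalize(cm)

    def test_dataset_profile_matches_brute_force(self):
        rng = np.random.default_rng(8)
        cm = make_cm(rng.integers(0, 100, (40, 3)))
        prof = dataset_profile(cm)
        arr = cm.values.to_numpy(dtype=float)
        brute = np.array(
            [row.mean() for row in arr]
        )
        brute = brute / brute.mean()
        np.testing.assert_allclose(prof, brute, rtol=1e-12)


def test_spike_sufficiency_filter():
    values = pd.DataFrame(
        {"deep": [600, 10], "shallow": [499, 10]},
        index=["ERCC-00001", "geneA"],
    )
    cm = CountMatrix(values)
    kept = filter_spike_sufficient(cm)
    assert list(kept.sample_ids) == ["deep"]
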