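import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stromasig import (AnalysisError, ExpressionMatrix, fold_change,
                       signature, univariate_de)
from stromasig.diffexp import P_FLOOR


def matrix_from_groups(cancer_rows, normal_rows, genes=None):
    cancer_rows = np.atleast_2d(cancer_rows)
    normal_rows = np.atleast_2d(normal_rows)
    values = np.hstack([cancer_rows, normal_rows])
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = ([f"c{i}" for i in range(cancer_rows.shape[1])]
            + [f"n{i}" for i in range(normal_rows.shape[1])])
    labels = (["cancer"] * cancer_rows.shape[1]
              + ["normal"] * normal_rows.shape[1])
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols),
                            labels)


def exhaustive_permutation_p(values, n_cancer):
    """Two-sided permutation p over all label reassignments (Welch t)."""
    idx = np.arange(values.size)
    t_obs = abs(stats.ttest_ind(values[:n_cancer], values[n_cancer:],
                                equal_var=False).statistic)
    count = total = 0
    for combo in itertools.combinations(idx, n_cancer):
        mask = np.zeros(values.size, dtype=bool)
        mask[list(combo)] = True
        t = abs(stats.ttest_ind(values[mask], values[~mask],
                                equal_var=False).statistic)
        count += t >= t_obs - 1e-12
        total += 1
    return count / total


class TestUnivariateDE:
    def test_constant_gene_gets_p_one_fc_one(self):
        m = matrix_from_groups([[5.0, 5.0, 5.0]], [[5.0, 5.0, 5.0]])
        de = univariate_de(m)
        assert de.loc["g0", "p_value"] == 1.0
        assert de.loc["g0", "fold_change"] == 1.0

    @pytest.mark.parametrize("test", ["pooled", "welch"])
    def test_worked_example_2_3_4_vs_6_7_8(self, test):
        """Pooled t = -4.899 on 4 df gives two-sided p close to 0.0081."""
        m = matrix_from_groups([[2.0, 3.0, 4.0]], [[6.0, 7.0, 8.0]])
        de = univariate_de(m, test=test)
        expected = 2 * stats.t.sf(4.0 / np.sqrt(2.0 / 3.0), df=4)
        assert de.loc["g0", "p_value"] == pytest.approx(expected, rel=1e-9)
        assert de.loc["g0", "p_value"] == pytest.approx(0.0081, abs=2e-4)
        assert de.loc["g0", "direction"] == "down"
        assert de.loc["g0", "fold_change"] == pytest.approx(-16.0)

    def test_matches_exhaustive_permutation_on_4v4_toys(self, rng):
        """Welch p tracks the exact label-permutation p on small toys."""
        diffs = []
        for _ in range(40):
            vals = rng.normal(0, 1, 8) + np.r_[np.zeros(4),
                                               rng.normal(0, 0.8, 4)]
            m = matrix_from_groups([vals[:4]], [vals[4:]])
            p_t = univariate_de(m).loc["g0", "p_value"]
            p_perm = exhaustive_permutation_p(vals, 4)
            diffs.append(abs(p_t - p_perm))
        assert max(diffs) < 0.2
        assert np.mean(diffs) < 0.08

    def test_class_with_one_sample_is_error(self):
        m = matrix_from_groups([[1.0, 2.0, 3.0]], [[9.0]])
        with pytest.raises(AnalysisError):
            univariate_de(m)

    def test_zero_variance_shifted_gene_is_floored_not_nan(self):
        m = matrix_from_groups([[4.0, 4.0]], [[6.0, 6.0]])
        de = univariate_de(m)
        assert de.loc["g0", "p_value"] == P_FLOOR
        assert de.loc["g0", "direction"] == "down"

    def test_label_swap_maps_up_to_down_and_keeps_p(self, rng):
        vals = rng.normal(8, 1, (50, 10))
        genes = [f"g{i}" for i in range(50)]
        cols = [f"s{i}" for i in range(10)]
        labels = ["cancer"] * 5 + ["normal"] * 5
        swapped = ["normal"] * 5 + ["cancer"] * 5
        frame = pd.DataFrame(vals, index=genes, columns=cols)
        de1 = univariate_de(ExpressionMatrix(frame, labels))
        de2 = univariate_de(ExpressionMatrix(frame, swapped))
        np.testing.assert_allclose(de1["p_value"], de2["p_value"])
        np.testing.assert_allclose(de1["fold_change"], -de2["fold_change"])

    def test_null_pvalues_are_uniform(self, rng):
        """Global null: per-gene p from 1500 null genes passes a KS test."""
        vals = rng.normal(0, 1, (1500, 26))
        m = matrix_from_groups(vals[:, :20], vals[:, 20:])
        de = univariate_de(m)
        ks = stats.kstest(de["p_value"], "uniform")
        assert ks.pvalue > 0.01


class TestFoldChange:
    def test_forced_examples(self):
        assert fold_change(5.0, 5.0) == 1.0
        assert fold_change(6.0, 5.0) == 2.0
        assert fold_change(3.0, 5.0) == -4.0

    def test_planted_25_fold_repression_recovered_at_low_noise(self):
        """A gene 25-fold down in tumor epithelium reads out near -25."""
        from stromasig import CohortConfig, simulate_cohort
        cfg = CohortConfig(
            n_genes=200, n_epithelial_up=0, n_epithelial_down=40,
            n_stromal=0, n_cn_gain=0, n_cn_loss=0,
            effect_log2_low=np.log2(25.0), effect_log2_high=np.log2(25.0),
            effect_penetrance=1.0, dropout_rate=0.0, noise_sd_log2=0.05,
            purity_micro=1.0, seed=4)
        c = simulate_cohort(cfg)
        down = c.truth.roles.loc[c.truth.roles.role == "epithelial_down",
                                 "gene"]
        tumor_mean = c.micro.values.loc[down].mean(axis=1)
        normal_mean = c.normals.values.loc[down].mean(axis=1)
        fcs = np.array([fold_change(t, n)
                        for t, n in zip(tumor_mean, normal_mean)])
        assert np.median(np.abs(fcs + 25.0)) < 2.5

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(-10, 10), b=st.floats(-10, 10), c=st.floats(-5, 5))
    def test_antisymmetry_and_shift_equivariance(self, a, b, c):
        if a != b:
            assert fold_change(a, b) == pytest.approx(-fold_change(b, a))
        assert fold_change(a + c, b + c) == pytest.approx(fold_change(a, b))


class TestSignature:
    def test_threshold_split_and_conservation(self):
        de = pd.DataFrame(
            {"p_value": [1e-7, 1e-7, 0.2, 0.5],
             "fold_change": [2.0, -3.0, 1.5, 1.0],
             "direction": ["up", "down", "up", "up"]},
            index=["A", "B", "C", "D"])
        up, down = signature(de, 1e-6)
        assert up.members == {"A"} and down.members == {"B"}
        n_hits = (de["p_value"] < 1e-6).sum()
        assert len(up) + len(down) == n_hits

    def test_all_null_gives_empty_sets(self):
        de = pd.DataFrame({"p_value": [0.5] * 3, "fold_change": [1.0] * 3,
                           "direction": ["up"] * 3}, index=list("ABC"))
        up, down = signature(de, 1e-6)
        assert len(up) == 0 and len(down) == 0

    def test_alpha_bounds(self):
        de = pd.DataFrame({"p_value": [0.5], "fold_change": [1.0],
                           "direction": ["up"]}, index=["A"])
        with pytest.raises(AnalysisError):
            signature(de, 1.0)
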