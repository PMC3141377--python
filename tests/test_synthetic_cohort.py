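import numpy as np
import pandas as pd
import pytest

from stromasig import (CohortConfig, ConfigError, cross_method_correlation,
                       planted_sets, simulate_cohort)


def degenerate(purity, **kw):
    """Config with exact purity, no dropout, no noise."""
    return CohortConfig(
        n_genes=300, n_epithelial_up=15, n_epithelial_down=15, n_stromal=20,
        n_cn_gain=5, n_cn_loss=5, amplicon_genes=5,
        purity_macro_median=purity, purity_macro_iqr=(purity, purity),
        purity_micro=1.0, dropout_rate=0.0, noise_sd_log2=0.0, seed=11, **kw)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(n_genes=200, n_epithelial_up=10,
                           n_epithelial_down=10, n_stromal=10, n_cn_gain=5,
                           n_cn_loss=5, amplicon_genes=5, seed=3)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.macro.values.to_csv() == b.macro.values.to_csv()
        assert a.micro.values.to_csv() == b.micro.values.to_csv()
        assert a.normals.values.to_csv() == b.normals.values.to_csv()
        assert a.cgh[0].probes.to_csv() == b.cgh[0].probes.to_csv()
        pd.testing.assert_frame_equal(a.truth.roles, b.truth.roles)

    def test_different_seed_differs(self):
        cfg = CohortConfig(n_genes=200, n_epithelial_up=10,
                           n_epithelial_down=10, n_stromal=10, n_cn_gain=5,
                           n_cn_loss=5, amplicon_genes=5)
        a = simulate_cohort(cfg, seed=1)
        b = simulate_cohort(cfg, seed=2)
        assert not np.allclose(a.macro.values, b.macro.values)

    def test_truth_round_trips_through_json(self, tmp_path):
        from stromasig import SyntheticTruth
        c = simulate_cohort(degenerate(0.5))
        path = tmp_path / "truth.json"
        c.truth.to_json(path)
        again = SyntheticTruth.from_json(path)
        pd.testing.assert_frame_equal(c.truth.roles, again.roles)
        pd.testing.assert_frame_equal(c.truth.dropout_mask, again.dropout_mask)
        assert again.config.seed == c.truth.config.seed


class TestMixtureModel:
    def test_pure_epithelium_makes_macro_equal_micro(self):
        c = simulate_cohort(degenerate(1.0))
        np.testing.assert_allclose(c.macro.values.to_numpy(),
                                   c.micro.values.to_numpy())

    def test_zero_purity_macro_is_the_stromal_profile(self):
        c = simulate_cohort(degenerate(0.0))
        roles = c.truth.roles.set_index("gene")
        baseline = c.normals.values.iloc[:, 0]  # noise-free normals = baseline
        expected = baseline + roles["stromal_boost"]
        for col in c.macro.values.columns:
            np.testing.assert_allclose(c.macro.values[col], expected)

    def test_stromal_gene_decreases_with_purity(self):
        c = simulate_cohort(degenerate(0.5))
        order = np.argsort(c.truth.purity["purity_macro"].to_numpy())
        roles = c.truth.roles
        stromal = roles.loc[roles["role"] == "stromal_specific", "gene"]
        vals = c.macro.values.loc[stromal].to_numpy()[:, order]
        assert (np.diff(vals, axis=1) < 0).all()

    def test_dropout_fraction_matches_rate(self):
        c = simulate_cohort(CohortConfig(seed=1))
        mask = c.truth.dropout_mask.to_numpy()
        frac = mask.mean()
        n = mask.size
        half_width = 3.5 * np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.30) < half_width
        # the mask is what was actually applied to the matrix
        floored = (c.micro.values.to_numpy()
                   == c.truth.config.dropout_floor_log2)
        assert (floored >= mask).all()


class TestCorrelationStructure:
    def test_perfect_pairing_when_nothing_degrades(self):
        c = simulate_cohort(degenerate(1.0))
        corr = cross_method_correlation(c.macro, c.micro)
        np.testing.assert_allclose(corr.per_patient.to_numpy(), 1.0)

    def test_correlation_drops_with_stromal_contamination(self):
        kw = dict(n_genes=400, n_epithelial_up=20, n_epithelial_down=20,
                  n_stromal=40, n_cn_gain=10, n_cn_loss=10, amplicon_genes=5)
        meds = {}
        for purity in (0.3, 0.9):
            cfg = CohortConfig(purity_macro_median=purity,
                               purity_macro_iqr=(purity - 0.05, purity + 0.05),
                               seed=5, **kw)
            c = simulate_cohort(cfg)
            meds[purity] = cross_method_correlation(c.macro, c.micro).median
        assert meds[0.3] < meds[0.9]


class TestTruthAndSets:
    def test_roles_partition_the_genome(self, small_cohort):
        counts = small_cohort.truth.roles["role"].value_counts()
        assert counts.sum() == small_cohort.truth.config.n_genes
        assert counts["epithelial_up"] == 20
        assert counts["epithelial_down"] == 20
        assert counts["stromal_specific"] == 30

    def test_effect_sign_matches_role(self, small_cohort):
        roles = small_cohort.truth.roles
        assert (roles.loc[roles.role == "epithelial_up", "effect_log2"] > 0).all()
        assert (roles.loc[roles.role == "epithelial_down", "effect_log2"] < 0).all()
        neutral = roles.role.isin(["housekeeping", "stromal_specific"])
        assert (roles.loc[neutral, "effect_log2"] == 0).all()
        assert roles.loc[roles.cn_driven, "role"].isin(
            ["epithelial_up", "epithelial_down"]).all()

    def test_planted_sets_sizes_and_absence(self, small_cohort):
        sets = {s.name: s for s in planted_sets(small_cohort.truth)}
        assert len(sets["cn_gain"]) == 10
        assert len(sets["epithelial_up"]) == 20
        assert sets["cn_gain"].members <= sets["epithelial_up"].members
        # no cn-driven genes -> cn sets absent, not empty
        cfg = CohortConfig(n_genes=100, n_epithelial_up=5,
                           n_epithelial_down=5, n_stromal=5,
                           n_cn_gain=0, n_cn_loss=0, seed=2)
        none = planted_sets(simulate_cohort(cfg).truth)
        assert {s.name for s in none} == {"epithelial_up", "epithelial_down"}

    def test_segments_respect_detectability_floor(self, small_cohort):
        segs = small_cohort.truth.segments
        assert (segs["log2"].abs() >= 0.55).all()
        assert (segs["log2"].abs() <= 1.5).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cohort(CohortConfig(dropout_rate=1.5))
        with pytest.raises(ConfigError):
            simulate_cohort(CohortConfig(noise_sd_log2=float("nan")))
        with pytest.raises(ConfigError):
            simulate_cohort(CohortConfig(n_tumor=1))
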