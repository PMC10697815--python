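"""Normalization, association model and diagnostics against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvpqtl.association import (adjust_covariates, bonferroni_threshold,
                                 classify_cis_trans, compare_inflation,
                                 filter_testable, fisher_cis_trans,
                                 fit_association, genomic_inflation,
                                 inverse_normal_transform)
from cnvpqtl.core import GenomicInterval


def series(vals):
    return pd.Series(vals, index=[f"s{i}" for i in range(len(vals))])


class TestAdjustCovariates:
    def covars(self, n, rng):
        return (series(rng.uniform(30, 70, n)),
                series(rng.integers(0, 2, n).astype(float)),
                series(rng.integers(0, 3, n)))

    def test_protein_equal_to_age_residualizes_to_zero(self):
        rng = np.random.default_rng(0)
        age, sex, batch = self.covars(50, rng)
        resid = adjust_covariates(age.copy(), age, sex, batch)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_independent_protein_keeps_variance(self):
        rng = np.random.default_rng(1)
        age, sex, batch = self.covars(1000, rng)
        y = series(rng.normal(size=1000))
        resid = adjust_covariates(y, age, sex, batch)
        assert resid.var() == pytest.approx(y.var(), rel=0.05)

    def test_single_batch_level_drops_term(self):
        rng = np.random.default_rng(2)
        age, sex, _ = self.covars(30, rng)
        batch = series(np.zeros(30, dtype=int))
        with pytest.warns(UserWarning, match="batch"):
            resid = adjust_covariates(series(rng.normal(size=30)), age, sex, batch)
        assert resid.notna().all()

    def test_missing_values_propagate(self):
        rng = np.random.default_rng(3)
        age, sex, batch = self.covars(30, rng)
        y = series(rng.normal(size=30))
        y.iloc[5] = np.nan
        resid = adjust_covariates(y, age, sex, batch)
        assert np.isnan(resid.iloc[5]) and resid.notna().sum() == 29


class TestInverseNormalTransform:
    def test_three_values_match_blom_quantiles(self):
        out = inverse_normal_transform(series([5.1, 2.0, 9.7]))
        # pre-standardization z at ranks (2,1,3): [0, -0.8694, +0.8694]
        z = stats.norm.ppf((np.array([2, 1, 3]) - 0.375) / 3.25)
        assert z[2] == pytest.approx(0.8694, abs=1e-4)
        assert np.allclose(out.to_numpy(), [0.0, -1.0, 1.0], atol=1e-12)

    def test_moments_exact(self):
        rng = np.random.default_rng(4)
        out = inverse_normal_transform(series(rng.normal(size=101)))
        assert abs(out.mean()) < 1e-8
        assert abs(out.std(ddof=1) - 1.0) < 1e-8

    def test_middle_value_of_odd_sample_maps_to_zero(self):
        out = inverse_normal_transform(series([10.0, 30.0, 7.0, 99.0, 15.0]))
        # 15.0 is the median (rank 3 of 5) and must land exactly at 0
        assert out.iloc[4] == pytest.approx(0.0, abs=1e-12)

    def test_idempotent_on_distinct_values(self):
        rng = np.random.default_rng(5)
        once = inverse_normal_transform(series(rng.normal(size=80)))
        twice = inverse_normal_transform(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_all_tied_errors(self):
        with pytest.raises(ValueError, match="tied"):
            inverse_normal_transform(series([1.0, 1.0, 1.0, 1.0]))


class TestFilterTestable:
    @pytest.mark.parametrize("n_carriers, expected", [(2, False), (3, True)])
    def test_carrier_boundary(self, n_carriers, expected):
        cn = np.full(10, 2.0)
        cn[:n_carriers] = 1.0
        y = np.zeros(10)
        assert filter_testable(cn, y) is expected

    def test_missing_protein_disqualifies_carrier(self):
        cn = np.full(10, 2.0)
        cn[:5] = 1.0
        y = np.zeros(10)
        y[:3] = np.nan  # 3 of the 5 carriers unmeasured
        assert filter_testable(cn, y) is False


class TestFitAssociation:
    def test_closed_form_df1(self):
        rec = fit_association(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.0, 3.0]),
                              pcs=None, n_pcs=0)
        assert rec.beta == pytest.approx(1.5, abs=1e-12)
        assert rec.se == pytest.approx(np.sqrt(0.75), abs=1e-12)
        assert rec.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_exact_linear_relation(self):
        cn = np.array([0.0, 1.0, 2.0, 3.0, 2.0])
        rec = fit_association(cn, 2.0 + 0.5 * cn, pcs=None, n_pcs=0)
        assert rec.beta == pytest.approx(0.5, abs=1e-10)

    def test_constant_cn_errors(self):
        with pytest.raises(ValueError, match="CN variance"):
            fit_association(np.full(10, 2.0), np.zeros(10), pcs=None, n_pcs=0)

    def test_planted_effect_recovered_within_3_se(self):
        rng = np.random.default_rng(6)
        n = 500
        cn = 2.0 - rng.binomial(2, 0.2, size=n)
        pcs = rng.normal(size=(n, 4))
        y = 0.8 * cn + pcs @ np.array([0.1, -0.2, 0.05, 0.0]) + rng.normal(size=n)
        rec = fit_association(cn, y, pcs, n_pcs=4)
        assert abs(rec.beta - 0.8) < 3 * rec.se

    def test_invariant_to_affine_pc_rescaling(self):
        rng = np.random.default_rng(7)
        n = 200
        cn = 2.0 + rng.binomial(2, 0.3, size=n)
        pcs = rng.normal(size=(n, 4))
        y = 0.4 * cn + pcs @ rng.normal(size=4) + rng.normal(size=n)
        a = fit_association(cn, y, pcs, n_pcs=4)
        b = fit_association(cn, y, pcs * np.array([3.0, -2.0, 10.0, 0.5]) + 7.0,
                            n_pcs=4)
        assert a.beta == pytest.approx(b.beta, rel=1e-9)
        assert a.se == pytest.approx(b.se, rel=1e-9)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_carrier_counts_by_direction(self):
        cn = np.array([2.0, 1.0, 0.0, 3.0, 2.0, 2.0])
        y = np.arange(6, dtype=float)
        rec = fit_association(cn, y, pcs=None, n_pcs=0)
        assert (rec.n_carriers, rec.n_deleted, rec.n_duplicated) == (3, 2, 1)


class TestThresholdAndEnrichment:
    def test_bonferroni_values(self):
        assert bonferroni_threshold(1) == 0.05
        assert bonferroni_threshold(10**6) == pytest.approx(5e-8)

    @pytest.mark.parametrize(
        "window, gene, expected",
        [
            (GenomicInterval("1", 0, 1000), GenomicInterval("1", 1_500_000, 1_501_000), "cis"),
            (GenomicInterval("1", 0, 1000), GenomicInterval("2", 100, 200), "trans"),
            (GenomicInterval("1", 0, 1000), GenomicInterval("1", 2_501_000, 2_502_000), "trans"),
        ],
    )
    def test_cis_trans_classification(self, window, gene, expected):
        assert classify_cis_trans(window, gene) == expected

    def test_unknown_gene_gives_missing_label(self):
        assert classify_cis_trans(GenomicInterval("1", 0, 1000), None) is None

    def test_fisher_balanced_table_is_one(self):
        assert fisher_cis_trans(5, 5, 5, 5) == 1.0

    def test_fisher_extreme_table_matches_hypergeometric_enumeration(self):
        from math import comb
        expected = 2.0 / comb(20, 10)
        assert fisher_cis_trans(0, 10, 10, 0) == pytest.approx(expected, rel=1e-9)

    def test_fisher_zero_margin_is_one(self):
        assert fisher_cis_trans(0, 0, 10, 5) == 1.0


class TestInflation:
    def test_all_half_gives_lambda_one(self):
        assert genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_chi2_of_one_gives_inverse_null_median(self):
        p = np.full(100, 2 * stats.norm.sf(1.0))  # chi-square stat exactly 1
        assert genomic_inflation(p) == pytest.approx(1 / 0.454936, rel=1e-4)

    def test_uniform_null_is_calibrated(self):
        rng = np.random.default_rng(8)
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_kruskal_wallis_example(self):
        assert compare_inflation([1, 2, 3], [4, 5, 6]) == pytest.approx(0.0495, abs=5e-4)

    def test_label_permutation_invariance(self):
        a, b = [1.1, 1.3, 0.9], [1.0, 1.2, 1.4]
        assert compare_inflation(a, b) == compare_inflation(b, a)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            compare_inflation([1.0], [1.0, 2.0])
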