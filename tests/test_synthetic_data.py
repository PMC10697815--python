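"""Generator calibration: HWE, Poisson depth moments, effect recovery, LD."""

import numpy as np
import pytest

from cnvpqtl.core import GenomicInterval
from cnvpqtl.synthetic_data import (EffectSpec, SimConfig, TruthRegion,
                                    default_sim_config, simulate_calls,
                                    simulate_genotypes, simulate_longread_calls,
                                    simulate_proteins, simulate_read_depth,
                                    simulate_snps)
from cnvpqtl.clump_ld import spearman_r2


def one_region_config(af=0.3, sv="deletion", n=1000, seed=0, jitter=0, **kw):
    region = TruthRegion("R0", GenomicInterval("1", 40_000, 45_000), sv, af,
                         breakpoint_jitter_sd=jitter)
    return SimConfig(n_samples=n, chromosome_lengths={"1": 100_000},
                     regions=[region], seed=seed, **kw)


class TestGenotypes:
    def test_zero_frequency_gives_all_wildtype(self):
        cfg = one_region_config(af=0.0, n=100)
        truth = simulate_genotypes(cfg)
        assert np.all(truth.cn == 2.0) and not truth.realized

    def test_hwe_carrier_fraction_matches_closed_form(self):
        q = 0.3
        n = 10_000
        cfg = one_region_config(af=q, n=n, seed=1)
        truth = simulate_genotypes(cfg)
        expected = 1 - (1 - q) ** 2  # 0.51
        frac = truth.carrier_matrix().mean()
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * sigma

    def test_seed_fixed_gives_identical_output(self):
        cfg = default_sim_config(seed=11, n_samples=50)
        a, b = simulate_genotypes(cfg), simulate_genotypes(cfg)
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(a.cn, b.cn)
        assert a.realized == b.realized
        assert simulate_calls(a, cfg) == simulate_calls(b, cfg)

    def test_jitter_shared_between_alleles_and_bounded(self):
        cfg = one_region_config(af=0.5, n=200, seed=2, jitter=100)
        truth = simulate_genotypes(cfg)
        widths = [iv.width for iv in truth.realized.values()]
        assert min(widths) > 0
        assert np.std([iv.start for iv in truth.realized.values()]) > 0


class TestReadDepth:
    def test_diploid_bin_mean_matches_poisson_moments(self):
        cfg = one_region_config(af=0.0, n=1, mean_depth=30.0)
        truth = simulate_genotypes(cfg)
        depth, _ = simulate_read_depth(truth, cfg, 0)
        bins = depth["1"].reshape(-1, 100).sum(axis=1)
        expected = 30.0 * 100
        sigma = np.sqrt(expected / len(bins))
        assert abs(bins.mean() - expected) < 3 * sigma

    def test_hom_deletion_region_has_zero_depth(self):
        cfg = one_region_config(af=0.999999, n=1, seed=3, mean_depth=30.0)
        truth = simulate_genotypes(cfg)
        assert truth.cn[0, 0] == 0.0
        depth, _ = simulate_read_depth(truth, cfg, 0)
        iv = truth.realized[(0, 0)]
        assert depth["1"][iv.start:iv.end].sum() == 0

    def test_cn4_region_doubles_depth_ratio(self):
        cfg = one_region_config(af=0.999999, sv="duplication", n=1, seed=4,
                                mean_depth=30.0)
        truth = simulate_genotypes(cfg)
        assert truth.cn[0, 0] == 4.0
        depth, _ = simulate_read_depth(truth, cfg, 0)
        iv = truth.realized[(0, 0)]
        inside = depth["1"][iv.start:iv.end].mean()
        outside = np.concatenate([depth["1"][:iv.start], depth["1"][iv.end:]]).mean()
        assert inside / outside == pytest.approx(2.0, rel=0.05)

    def test_q0_mass_injected_in_designated_region(self):
        q0_iv = GenomicInterval("1", 10_000, 12_000)
        cfg = one_region_config(af=0.0, n=1, q0_regions=[(q0_iv, 0.8)])
        truth = simulate_genotypes(cfg)
        _, q0 = simulate_read_depth(truth, cfg, 0)
        assert np.all(q0["1"][10_000:12_000] == 0.8)
        assert np.all(q0["1"][:10_000] == cfg.q0_baseline)


class TestProteins:
    def test_planted_effect_recovered_by_ols(self):
        cfg = one_region_config(af=0.1, n=500, seed=5,
                                effects=[EffectSpec("R0", "P000", 0.8)])
        truth = simulate_genotypes(cfg)
        cohort = simulate_proteins(truth, cfg)
        y = cohort.proteins["P000"].to_numpy()
        ok = ~np.isnan(y)
        X = np.column_stack([np.ones(ok.sum()), truth.cn[ok, 0]])
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ beta
        se = np.sqrt(resid @ resid / (ok.sum() - 2)
                     * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1] - 0.8) < 3 * se

    def test_noise_free_effect_is_exact(self):
        cfg = one_region_config(
            af=0.2, n=50, seed=6,
            effects=[EffectSpec("R0", "P000", 0.8)],
            protein_noise_sd=0.0, pc_effect_sd=0.0, age_effect_sd=0.0,
            sex_effect_sd=0.0, batch_effect_sd=0.0, protein_missing_rate=0.0,
        )
        truth = simulate_genotypes(cfg)
        cohort = simulate_proteins(truth, cfg)
        assert np.allclose(cohort.proteins["P000"], 0.8 * truth.cn[:, 0])

    def test_tables_share_sample_index(self):
        cfg = default_sim_config(seed=7, n_samples=40)
        truth = simulate_genotypes(cfg)
        cohort = simulate_proteins(truth, cfg)
        assert list(cohort.proteins.index) == cfg.sample_ids
        assert list(cohort.pcs.index) == cfg.sample_ids


class TestSnps:
    def ld(self, target, n=1000, seed=8, af=0.3):
        cfg = one_region_config(af=af, n=n, seed=seed,
                                snp_ld_targets={"R0": target})
        truth = simulate_genotypes(cfg)
        snps, positions = simulate_snps(truth, cfg)
        carrier = truth.carrier_matrix()[:, 0].astype(float)
        return spearman_r2(snps.iloc[:, 0].to_numpy(), carrier), positions

    def test_target_one_is_exact_copy(self):
        r2, _ = self.ld(1.0)
        assert r2 == pytest.approx(1.0)

    def test_target_zero_is_independent(self):
        r2, _ = self.ld(0.0)
        assert r2 < 0.05

    def test_target_intermediate_within_band(self):
        r2, _ = self.ld(0.8)
        assert 0.7 <= r2 <= 0.9

    def test_snp_placed_near_region(self):
        _, positions = self.ld(0.5)
        chrom, pos = positions["snp_R0"]
        assert chrom == "1" and pos == 55_000


class TestLongRead:
    def test_full_sensitivity_emits_every_deletion_carrier(self):
        cfg = one_region_config(af=0.3, n=200, seed=9,
                                longread_sensitivity={"deletion": 1.0,
                                                      "duplication": 0.0})
        truth = simulate_genotypes(cfg)
        records, yields = simulate_longread_calls(truth, cfg)
        carriers = {cfg.sample_ids[i] for i in np.flatnonzero(truth.dosage[:, 0])}
        with_rec = {s for s, recs in records.items() if recs}
        assert with_rec == carriers
        assert len(yields) == 200

    def test_zero_sensitivity_emits_no_duplications(self):
        cfg = one_region_config(af=0.3, sv="duplication", n=200, seed=9,
                                longread_sensitivity={"deletion": 1.0,
                                                      "duplication": 0.0})
        truth = simulate_genotypes(cfg)
        records, _ = simulate_longread_calls(truth, cfg)
        assert all(not recs for recs in records.values())

    def test_partial_sensitivity_is_binomial(self):
        cfg = one_region_config(af=0.3, n=400, seed=10,
                                longread_sensitivity={"deletion": 0.9,
                                                      "duplication": 0.0})
        truth = simulate_genotypes(cfg)
        n_carriers = int(truth.carrier_matrix().sum())
        records, _ = simulate_longread_calls(truth, cfg)
        emitted = sum(len(r) for r in records.values())
        sigma = np.sqrt(n_carriers * 0.9 * 0.1)
        assert abs(emitted - 0.9 * n_carriers) < 3 * sigma

    def test_dup_as_ins_emits_insertion_clusters(self):
        from cnvpqtl.core import SVType
        cfg = one_region_config(af=0.5, sv="duplication", n=100, seed=11,
                                longread_sensitivity={"deletion": 0.0,
                                                      "duplication": 1.0},
                                dup_as_ins_fraction=1.0)
        truth = simulate_genotypes(cfg)
        records, _ = simulate_longread_calls(truth, cfg)
        all_recs = [r for recs in records.values() for r in recs]
        assert all_recs and all(r.sv_type is SVType.INS for r in all_recs)
        assert all(r.interval.width == 1 for r in all_recs)
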