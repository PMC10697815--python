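"""Yield QC, interval equivalence rules and concordance accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cnvpqtl.core import Genotype, GenomicInterval, SVRecord, SVType
from cnvpqtl.longread_concord import (classify_concordance, coverage_qc,
                                      match_calls, reciprocal_overlap,
                                      summarize_validation)


def sv(sample, svtype, start, end, chrom="1"):
    return SVRecord(sample, svtype, GenomicInterval(chrom, start, end),
                    Genotype.HET, "test")


class TestCoverageQC:
    def test_boundary_at_30_gbp(self):
        qc = {s.sample_id: s.passed
              for s in coverage_qc({"a": 29.9, "b": 30.0, "c": 45.0})}
        assert qc == {"a": False, "b": True, "c": True}

    def test_fifteen_samples_three_below_leaves_twelve(self):
        yields = {f"s{i}": (20.0 if i < 3 else 40.0) for i in range(15)}
        assert sum(s.passed for s in coverage_qc(yields)) == 12


class TestReciprocalOverlap:
    def test_identical_is_one(self):
        a = GenomicInterval("1", 0, 100)
        assert reciprocal_overlap(a, a) == 1.0

    def test_half_shifted_is_half(self):
        assert reciprocal_overlap(GenomicInterval("1", 0, 100),
                                  GenomicInterval("1", 50, 150)) == 0.5

    def test_disjoint_and_cross_chromosome_are_zero(self):
        a = GenomicInterval("1", 0, 100)
        assert reciprocal_overlap(a, GenomicInterval("1", 200, 300)) == 0.0
        assert reciprocal_overlap(a, GenomicInterval("2", 0, 100)) == 0.0

    @given(st.integers(0, 400), st.integers(1, 400))
    def test_symmetric(self, start, width):
        a = GenomicInterval("1", 100, 300)
        b = GenomicInterval("1", start, start + width)
        assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)

    def test_monotone_as_interval_slides_away(self):
        a = GenomicInterval("1", 0, 100)
        ros = [reciprocal_overlap(a, GenomicInterval("1", s, s + 100))
               for s in range(0, 200, 10)]
        assert all(x >= y for x, y in zip(ros, ros[1:]))


class TestMatchCalls:
    def test_reciprocal_96_percent_matches(self):
        rec = sv("s", SVType.DEL, 100, 4900)
        assert match_calls(GenomicInterval("1", 0, 5000), "deletion", [rec]) == [rec]

    def test_inconsistent_direction_never_matches(self):
        rec = sv("s", SVType.DEL, 0, 5000)
        assert match_calls(GenomicInterval("1", 0, 5000), "duplication", [rec]) == []

    def test_insertion_cluster_matches_duplication_only_in_1bp_mode(self):
        cluster = [sv("s", SVType.INS, p, p + 1) for p in (1000, 2000, 3000)]
        target = GenomicInterval("1", 0, 5000)
        assert match_calls(target, "duplication", cluster, mode="reciprocal_50") == []
        assert match_calls(target, "duplication", cluster, mode="any_1bp") == cluster

    def test_inversions_and_breakends_never_consistent(self):
        recs = [sv("s", SVType.INV, 0, 5000), sv("s", SVType.BND, 10, 11)]
        assert match_calls(GenomicInterval("1", 0, 5000), "deletion", recs,
                           mode="any_1bp") == []


def make_frame(cells, samples):
    return pd.DataFrame(cells, index=["1:1001-6000"], columns=samples)


INTERVALS = {"1:1001-6000": GenomicInterval("1", 1000, 6000)}


class TestClassifyConcordance:
    def classify(self, cn, recs, coverage=20.0, yield_gbp=40.0):
        qc = coverage_qc({"s": yield_gbp})
        frame = make_frame([[cn]], ["s"])
        return classify_concordance(frame, INTERVALS, {"s": recs}, qc,
                                    regional_coverage=coverage)[0]

    def test_deletion_carrier_with_matching_del_is_concordant(self):
        rec = self.classify(1.0, [sv("s", SVType.DEL, 1100, 5900)])
        assert rec.classification == "concordant"
        assert rec.long_state == "deletion"

    def test_wildtype_with_no_call_is_concordant(self):
        rec = self.classify(2.0, [])
        assert rec.short_state == "wildtype"
        assert rec.classification == "concordant"

    def test_duplication_with_only_del_overlap_is_discordant(self):
        rec = self.classify(3.0, [sv("s", SVType.DEL, 1000, 6000)])
        assert rec.classification == "discordant"

    def test_low_regional_coverage_is_not_assessable(self):
        rec = self.classify(1.0, [sv("s", SVType.DEL, 1000, 6000)], coverage=3.0)
        assert rec.classification == "not_assessable"
        assert rec.long_state == "low_coverage"

    def test_failed_yield_qc_is_not_assessable(self):
        rec = self.classify(1.0, [sv("s", SVType.DEL, 1000, 6000)], yield_gbp=20.0)
        assert rec.classification == "not_assessable"
        assert rec.sample_passed is False

    def test_missed_carrier_is_discordant(self):
        rec = self.classify(1.0, [])
        assert rec.classification == "discordant"
        assert rec.long_state == "none"


class TestSummarize:
    def run_cohort(self, cns, recs_by_sample, coverage=20.0):
        samples = list(recs_by_sample)
        qc = coverage_qc({s: 40.0 for s in samples})
        frame = make_frame([cns], samples)
        records = classify_concordance(frame, INTERVALS, recs_by_sample, qc,
                                       regional_coverage=coverage)
        return records, summarize_validation(records)

    def test_all_carriers_matched_validates_100(self):
        recs = {f"s{i}": [sv(f"s{i}", SVType.DEL, 1000, 6000)] for i in range(4)}
        _, summ = self.run_cohort([1.0] * 4, recs)
        row = summ.iloc[0]
        assert (row.n_del_carriers, row.n_discordant) == (4, 0)
        assert bool(row.validated_100)

    def test_na_carriers_do_not_block_validation(self):
        # 6 concordant, 2 below regional coverage among 8 carriers
        recs = {f"s{i}": [sv(f"s{i}", SVType.DEL, 1000, 6000)] for i in range(8)}
        cov = lambda cnv, sample: 3.0 if sample in ("s6", "s7") else 20.0
        _, summ = self.run_cohort([1.0] * 8, recs, coverage=cov)
        row = summ.iloc[0]
        assert (row.n_concordant, row.n_discordant, row.n_na) == (6, 0, 2)
        assert bool(row.validated_100)

    def test_no_assessed_carrier_does_not_validate(self):
        recs = {"s0": [], "s1": []}
        _, summ = self.run_cohort([2.0, 2.0], recs)
        assert not bool(summ.iloc[0].validated_100)

    def test_classification_counts_partition_passing_samples(self):
        recs = {f"s{i}": [] for i in range(6)}
        records, summ = self.run_cohort([1.0, 1.0, 2.0, 2.0, 3.0, np.nan], recs)
        row = summ.iloc[0]
        carriers_and_wt = row.n_concordant + row.n_discordant + row.n_na + row.n_wildtype
        defined = [r for r in records if r.sample_passed and r.short_state != "missing"]
        assert carriers_and_wt == len(defined) == 5


class TestAsymmetryInvariant:
    def test_perfect_del_and_absent_dup_sensitivity(self):
        """DEL sensitivity 1 makes every deletion carrier concordant; DUP
        sensitivity 0 makes every duplication carrier discordant."""
        from cnvpqtl.cnv_matrix import (build_window_grid, genotype_windows,
                                        merge_adjacent, merged_to_frame,
                                        qc_high_confidence, select_windows)
        from cnvpqtl.io_formats import parse_region
        from cnvpqtl.synthetic_data import (simulate_calls, simulate_genotypes,
                                            simulate_longread_calls,
                                            validation_sim_config)

        cfg = validation_sim_config(seed=1, n_regions_per_type=40)
        cfg.longread_sensitivity = {"deletion": 1.0, "duplication": 0.0}
        cfg.longread_low_yield_fraction = 0.0
        truth = simulate_genotypes(cfg)
        calls = simulate_calls(truth, cfg)
        hc = qc_high_confidence(calls, cfg.n_samples)
        sel = select_windows(hc, build_window_grid(cfg.chromosome_lengths))
        frame = merged_to_frame(
            merge_adjacent(genotype_windows(calls, sel, cfg.sample_ids)),
            cfg.sample_ids)
        recs, yields = simulate_longread_calls(truth, cfg)
        records = classify_concordance(
            frame, {r: parse_region(r) for r in frame.index}, recs,
            coverage_qc(yields))
        for r in records:
            if r.short_state == "deletion":
                assert r.classification == "concordant"
            elif r.short_state == "duplication":
                assert r.classification == "discordant"
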