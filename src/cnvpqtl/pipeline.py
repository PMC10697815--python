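"""End-to-end orchestration: calls -> CN matrix -> association -> clumps.

This is the programmatic equivalent of running the CLI stages in sequence,
and the surface the synthetic parameter-recovery checks exercise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .association import (AssociationRecord, TestPlan, normalize_proteins,
                          run_association_scan)
from .clump_ld import ClumpRecord, clump
from .cnv_matrix import (CNMatrix, MergedCNV, QCThresholds, build_window_grid,
                         genotype_windows, merge_adjacent, merged_to_frame,
                         qc_high_confidence, select_windows)
from .core import CohortTables, RawCall
from .synthetic_data import (GenotypeTruth, SimConfig, simulate_calls,
                             simulate_genotypes, simulate_proteins)


@dataclass
class PipelineResult:
    matrix: CNMatrix
    merged: list[MergedCNV]
    merged_frame: pd.DataFrame  # merged CNVs x samples
    records: list[AssociationRecord]
    plan: TestPlan
    significant: list[AssociationRecord]
    clumps: list[ClumpRecord]


def run_pipeline(
    calls: list[RawCall],
    cohort: CohortTables,
    chromosome_lengths: dict[str, int],
    thresholds: QCThresholds = QCThresholds(),
    n_pcs: int = 4,
    carrier_min: int = 3,
    alpha_family: float = 0.05,
    window_size: int = 200,
) -> PipelineResult:
    """Run matrix construction, association and clumping on a call set."""
    sample_ids = list(cohort.proteins.index)
    hc = qc_high_confidence(calls, n_samples=len(sample_ids), thresholds=thresholds)
    grid = build_window_grid(chromosome_lengths, window_size)
    selected = select_windows(hc, grid)
    matrix = genotype_windows(calls, selected, sample_ids, thresholds)
    merged = merge_adjacent(matrix)
    merged_frame = merged_to_frame(merged, sample_ids)
    normalized = normalize_proteins(cohort.proteins, cohort.covariates)
    records, plan = run_association_scan(
        merged_frame, normalized, cohort.pcs, n_pcs=n_pcs,
        carrier_min=carrier_min, alpha_family=alpha_family,
    )
    significant = [r for r in records if r.p_value < plan.threshold] \
        if plan.n_tests_performed else []
    cn_vectors = {region: merged_frame.loc[region].to_numpy(dtype=float)
                  for region in {r.region for r in significant}}
    clumps = clump(significant, cn_vectors)
    return PipelineResult(matrix, merged, merged_frame, records, plan,
                          significant, clumps)


def run_synthetic_pipeline(config: SimConfig) -> tuple[PipelineResult, GenotypeTruth]:
    """Simulate a cohort under *config* and run the full pipeline on it."""
    truth = simulate_genotypes(config)
    calls = simulate_calls(truth, config)
    cohort = simulate_proteins(truth, config)
    result = run_pipeline(calls, cohort, config.chromosome_lengths)
    return result, truth


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    false_positive_clumps: int
    threshold: float

    @property
    def all_recovered(self) -> bool:
        return self.n_recovered == self.n_planted


def evaluate_recovery(result: PipelineResult, config: SimConfig) -> RecoveryReport:
    """Compare significant clumps against the planted (region, protein) effects.

    A planted effect is recovered when some clump for that protein lies
    within the breakpoint-jitter extent (4 jitter SDs) of the truth region;
    carrier breakpoints scatter around the truth interval, so edge windows
    just outside it are still signal from the planted CNV. A clump is a
    false positive when its span is attributable to no planted region for
    its protein. Multiple clumps over one planted region (e.g. jitter edge
    windows flagged as unresolved) count as one recovery, not as false
    positives.
    """
    planted = []
    for e in config.effects:
        reg = config.region_by_id(e.region_id)
        planted.append((reg.interval, e.protein_id, 4 * reg.breakpoint_jitter_sd))
    recovered = set()
    false_pos = 0
    for c in result.clumps:
        hit = None
        for k, (iv, pid, margin) in enumerate(planted):
            dist = c.span.distance_to(iv)
            if c.protein_id == pid and dist is not None and dist <= margin:
                hit = k
                break
        if hit is None:
            false_pos += 1
        else:
            recovered.add(hit)
    return RecoveryReport(
        n_planted=len(planted),
        n_recovered=len(recovered),
        false_positive_clumps=false_pos,
        threshold=result.plan.threshold if result.plan.n_tests_performed else float("nan"),
    )
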