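"""From per-sample calls to the merged population copy-number matrix.

Two QC tiers: a strict one (per-sample Bonferroni on the call t-test, q0 <
0.5) nominates 200-bp windows; a lenient one (q0 only) genotypes every
sample in those windows, filling wild type with CN 2 and failed QC with NA.
Adjacent windows with identical columns merge into the final CNV units.
"""

from cnvpqtl.cnv_matrix import (build_window_grid, genotype_windows,
                                merge_adjacent, merged_to_frame,
                                qc_high_confidence, select_windows)
from cnvpqtl.synthetic_data import (default_sim_config, simulate_calls,
                                    simulate_genotypes)

config = default_sim_config(seed=1)
truth = simulate_genotypes(config)
calls = simulate_calls(truth, config)

high_conf = qc_high_confidence(calls, n_samples=config.n_samples)
grid = build_window_grid(config.chromosome_lengths)
selected = select_windows(high_conf, grid)
matrix = genotype_windows(calls, selected, config.sample_ids)
merged = merge_adjacent(matrix)
frame = merged_to_frame(merged, config.sample_ids)

print(f"{len(calls)} calls -> {len(high_conf)} high-confidence after strict QC")
print(f"{len(grid.windows)} genome windows -> {len(selected)} selected "
      f"-> {len(merged)} merged CNVs")
one = merged[0]
col = one.column_signature
print(f"first merged CNV {one.region}: "
      f"{(col != 2.0).sum()} carriers, CN range "
      f"{col.min():.2f}-{col.max():.2f}")
# Each merged CNV row of `frame` is one unit of association testing; cells
# hold the real-valued CN (exactly 2.0 = wild-type fill, NA = failed QC).
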