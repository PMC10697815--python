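"""Generate a synthetic cohort with planted CNV-protein effects.

The default study conditions: 500 samples, 30 polymorphic CNV regions over
three chromosomes, 20 plasma-protein-like traits, and two planted linear
effects of copy number on a protein (|beta| = 0.8 per CN unit).
"""

import numpy as np

from cnvpqtl.synthetic_data import (default_sim_config, simulate_calls,
                                    simulate_genotypes, simulate_proteins)

config = default_sim_config(seed=1)
truth = simulate_genotypes(config)
calls = simulate_calls(truth, config)
cohort = simulate_proteins(truth, config)

print(f"cohort: {config.n_samples} samples, {len(config.regions)} CNV regions, "
      f"{config.n_proteins} proteins")
print(f"true carrier fraction per region (mean): "
      f"{truth.carrier_matrix().mean():.3f}")
print(f"short-read call table: {len(calls)} calls "
      f"({sum(c.sv_type == 'deletion' for c in calls)} deletions)")
print(f"protein matrix: {cohort.proteins.shape}, "
      f"{np.isnan(cohort.proteins.to_numpy()).mean():.1%} missing")
for eff in config.effects:
    print(f"planted effect: {eff.beta:+.1f} per CN unit of {eff.region_id} "
          f"on {eff.protein_id}")
# Carrier fractions follow Hardy-Weinberg (1-(1-AF)^2); the call table is
# what a read-depth caller would report, including breakpoint jitter,
# CN noise and a handful of spurious low-significance calls.
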