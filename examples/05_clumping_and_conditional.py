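"""LD between a CNV and a nearby SNP, and the conditional analysis.

A SNP is simulated in controlled LD (target Spearman R^2 = 0.8) with a
planted CNV. The conditional fit adds the SNP allele counts as a covariate
and asks whether the CNV-protein association survives — distinguishing an
independent CNV signal from shadowing of a known SNP association.
"""

import numpy as np

from cnvpqtl.clump_ld import conditional_fit, spearman_r2
from cnvpqtl.association import fit_association, normalize_proteins
from cnvpqtl.synthetic_data import (default_sim_config, simulate_genotypes,
                                    simulate_proteins, simulate_snps)

config = default_sim_config(seed=2)
config.snp_ld_targets = {"R00": 0.8}
truth = simulate_genotypes(config)
cohort = simulate_proteins(truth, config)
snps, positions = simulate_snps(truth, config)

cn = truth.cn[:, 0]  # planted region R00 with beta +0.8 on P000
snp = snps["snp_R00"].to_numpy()
r2 = spearman_r2(cn, snp)
print(f"realized CNV-SNP LD: R^2 = {r2:.3f} (target 0.8)")

normalized = normalize_proteins(cohort.proteins, cohort.covariates)
y = normalized["P000"].to_numpy()
pcs = cohort.pcs.to_numpy()

uncond = fit_association(cn, y, pcs, n_pcs=4)
cond, retained = conditional_fit(cn, y, pcs, snp, n_pcs=4, threshold=1e-5)
print(f"unconditional: beta={uncond.beta:+.3f} p={uncond.p_value:.2e}")
print(f"conditional on the SNP: beta={cond.beta:+.3f} p={cond.p_value:.2e} "
      f"-> retains significance: {retained}")
# The SNP has no direct effect on the protein, so conditioning shifts the
# CN coefficient only within its standard error and the CNV signal stands.
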