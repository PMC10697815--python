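"""Synthetic cohorts with planted truth for end-to-end pipeline testing.

The generator emulates the data the pipeline consumes in the field:

* polymorphic CNV regions segregating under Hardy-Weinberg equilibrium,
  with real-valued copy numbers and per-sample breakpoint jitter;
* per-bp Poisson read-depth profiles whose expectation scales with CN/2
  (no GC or mappability structure beyond an injectable q0 mass);
* plasma-protein-like traits built as linear CN effects plus principal
  component, age, sex and batch structure plus Gaussian noise;
* SNPs in controlled LD with the CNV carrier status;
* long-read SV call sets with SV-type-dependent sensitivity (deletions
  recovered well, duplications poorly) and per-sample molecular yields.

All generators are pure functions of (config, seed): each operation derives
its RNG stream from ``config.seed`` and a fixed per-operation tag, so
calling operations in any order or in isolation is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import CohortTables, Genotype, GenomicInterval, RawCall, SVRecord, SVType

# fixed per-operation RNG stream tags
_STREAM = {"genotypes": 11, "depth": 12, "calls": 13, "proteins": 14,
           "snps": 15, "longread": 16}


@dataclass(frozen=True)
class TruthRegion:
    """A polymorphic CNV region with a population allele frequency."""

    region_id: str
    interval: GenomicInterval
    sv_type: str  # deletion | duplication
    allele_frequency: float
    cn_per_allele: float = 1.0  # copies lost/gained per alternate allele
    breakpoint_jitter_sd: int = 100  # bp; per-sample, shared by both alleles

    def __post_init__(self) -> None:
        if not (0 <= self.allele_frequency < 1):
            raise ValueError("allele_frequency must be in [0, 1)")
        if self.sv_type not in ("deletion", "duplication"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.breakpoint_jitter_sd < 0 or self.breakpoint_jitter_sd >= self.interval.width / 2:
            raise ValueError("jitter sd must be in [0, width/2)")

    @property
    def cn_delta_per_allele(self) -> float:
        return -self.cn_per_allele if self.sv_type == "deletion" else self.cn_per_allele


@dataclass(frozen=True)
class EffectSpec:
    """A planted linear effect of a region's CN on one protein."""

    region_id: str
    protein_id: str
    beta: float  # per CN unit, on the protein's raw scale

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int
    chromosome_lengths: dict[str, int]
    regions: list[TruthRegion]
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0
    mean_depth: float = 30.0  # reads per bp
    n_proteins: int = 20
    n_pcs: int = 4
    pc_effect_sd: float = 0.2
    age_effect_sd: float = 0.005
    sex_effect_sd: float = 0.2
    batch_effect_sd: float = 0.2
    n_batches: int = 4
    protein_noise_sd: float = 1.0
    protein_missing_rate: float = 0.02
    cn_noise_sd: float = 0.05  # noise on called CN around truth
    q0_baseline: float = 0.02
    q0_fail_rate: float = 0.02  # fraction of calls pushed above the q0 cutoff
    false_calls_per_sample: float = 1.0
    longread_sensitivity: dict[str, float] = field(
        default_factory=lambda: {"deletion": 0.9, "duplication": 0.2}
    )
    longread_jitter_sd: int = 30
    longread_yield_gbp: float = 40.0
    longread_low_yield_fraction: float = 0.0
    dup_as_ins_fraction: float = 0.0  # duplications emitted as INS clusters
    snp_ld_targets: dict[str, float] = field(default_factory=dict)
    q0_regions: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in (self.protein_missing_rate, self.q0_fail_rate,
                  self.longread_low_yield_fraction, self.dup_as_ins_fraction,
                  *self.longread_sensitivity.values(), *self.snp_ld_targets.values()):
            if not (0 <= p <= 1):
                raise ValueError(f"probability {p} outside [0, 1]")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]

    @property
    def protein_ids(self) -> list[str]:
        return [f"P{i:03d}" for i in range(self.n_proteins)]

    def region_by_id(self, region_id: str) -> TruthRegion:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)


def _rng(config: SimConfig, op: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM[op]])


@dataclass
class GenotypeTruth:
    """True diploid CN genotypes plus per-sample realized breakpoints."""

    dosage: np.ndarray  # (n_samples, n_regions) alternate-allele counts 0/1/2
    cn: np.ndarray  # (n_samples, n_regions) true copy numbers
    realized: dict[tuple[int, int], GenomicInterval]  # carriers only

    def carrier_matrix(self) -> np.ndarray:
        return self.dosage > 0


def simulate_genotypes(config: SimConfig) -> GenotypeTruth:
    """Draw diploid CNV genotypes under Hardy-Weinberg equilibrium.

    Per (sample, region) the alternate-allele dosage is Binomial(2, AF);
    CN = 2 + dosage x per-allele delta. Carrier breakpoints are the truth
    interval shifted by rounded Normal(0, jitter_sd) offsets, identical for
    the two alleles of one sample, clamped to the chromosome.
    """
    rng = _rng(config, "genotypes")
    n, R = config.n_samples, len(config.regions)
    dosage = np.zeros((n, R), dtype=np.int8)
    cn = np.full((n, R), 2.0)
    realized: dict[tuple[int, int], GenomicInterval] = {}
    for j, reg in enumerate(config.regions):
        dosage[:, j] = rng.binomial(2, reg.allele_frequency, size=n)
        cn[:, j] = 2.0 + dosage[:, j] * reg.cn_delta_per_allele
        np.clip(cn[:, j], 0.0, None, out=cn[:, j])
        carriers = np.flatnonzero(dosage[:, j])
        if reg.breakpoint_jitter_sd > 0:
            shifts = np.round(
                rng.normal(0.0, reg.breakpoint_jitter_sd, size=(len(carriers), 2))
            ).astype(int)
        else:
            shifts = np.zeros((len(carriers), 2), dtype=int)
        L = config.chromosome_lengths[reg.interval.chrom]
        for i, (ds, de) in zip(carriers, shifts):
            s = max(0, reg.interval.start + int(ds))
            e = min(L, reg.interval.end + int(de))
            if e <= s:
                s, e = reg.interval.start, reg.interval.end
            realized[(int(i), j)] = GenomicInterval(reg.interval.chrom, s, e)
    return GenotypeTruth(dosage, cn, realized)


def simulate_read_depth(
    truth: GenotypeTruth, config: SimConfig, sample_index: int
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-bp Poisson depth (and q0) profiles for one sample.

    Expected depth is ``mean_depth x CN/2`` inside the sample's realized
    CNV intervals and ``mean_depth`` elsewhere. The q0 profile is the
    baseline everywhere except the configured q0 regions.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng([config.seed, _STREAM["depth"], sample_index])
    depth: dict[str, np.ndarray] = {}
    q0: dict[str, np.ndarray] = {}
    for chrom, L in config.chromosome_lengths.items():
        lam = np.full(L, config.mean_depth)
        for j, reg in enumerate(config.regions):
            if reg.interval.chrom != chrom:
                continue
            iv = truth.realized.get((sample_index, j))
            if iv is None:
                continue
            lam[iv.start:iv.end] = config.mean_depth * truth.cn[sample_index, j] / 2.0
        depth[chrom] = rng.poisson(lam).astype(float)
        prof = np.full(L, config.q0_baseline)
        for iv, val in config.q0_regions:
            if iv.chrom == chrom:
                prof[iv.start:iv.end] = val
        q0[chrom] = prof
    return depth, q0


def _analytic_call_p(cn: float, width: int, mean_depth: float, bin_size: int = 100) -> float:
    """Expected one-sample t-test p for a call of this CN and width.

    Uses the Poisson moments of the binned depth: per-bin regional mean
    ``b x depth x CN/2`` with SD its square root, tested against the global
    per-bin mean over ``width/b`` bins.
    """
    n_bins = max(2, width // bin_size)
    lam_g = bin_size * mean_depth
    lam_r = max(bin_size * mean_depth * cn / 2.0, 0.25)
    t = (lam_r - lam_g) / (np.sqrt(lam_r) / np.sqrt(n_bins))
    p = 2.0 * stats.t.sf(abs(t), df=n_bins - 1)
    return float(min(max(p, 1e-300), 1.0))


def simulate_calls(truth: GenotypeTruth, config: SimConfig) -> list[RawCall]:
    """Short-read CNV call tables implied by the truth genotypes.

    Carrier (sample, region) pairs yield one call at the sample's realized
    breakpoints with CN = truth + Normal(0, cn_noise_sd) and a t-test
    p-value from the Poisson depth model; a configured fraction receive a
    failing q0 (>= 0.5). Spurious calls (Poisson-many per sample, small CN
    deviations at random positions) exercise the QC tiers.
    """
    rng = _rng(config, "calls")
    calls: list[RawCall] = []
    chroms = list(config.chromosome_lengths)
    for (i, j), iv in sorted(truth.realized.items()):
        reg = config.regions[j]
        true_cn = truth.cn[i, j]
        cn = true_cn + rng.normal(0.0, config.cn_noise_sd)
        cn = min(cn, 2.0 - 1e-3) if reg.sv_type == "deletion" else max(cn, 2.0 + 1e-3)
        cn = max(cn, 0.0)
        p = _analytic_call_p(true_cn, iv.width, config.mean_depth)
        if rng.random() < config.q0_fail_rate:
            q0 = rng.uniform(0.5, 1.0)
        else:
            q0 = min(rng.beta(1, 19), 0.49)
        calls.append(RawCall(config.sample_ids[i], reg.sv_type, iv, cn, p, q0))
    # spurious calls: weak CN shifts at random positions, mostly failing strict QC
    n_fp = rng.poisson(config.false_calls_per_sample, size=config.n_samples)
    for i, k in enumerate(n_fp):
        for _ in range(k):
            chrom = chroms[rng.integers(len(chroms))]
            L = config.chromosome_lengths[chrom]
            width = int(rng.integers(5, 16)) * 200
            start = int(rng.integers(0, max(1, L - width)))
            sv = "deletion" if rng.random() < 0.5 else "duplication"
            cn = 2.0 - rng.uniform(0.15, 0.45) if sv == "deletion" else \
                2.0 + rng.uniform(0.15, 0.45)
            p = float(10 ** rng.uniform(-6, -1))
            q0 = min(rng.beta(1, 19), 0.49)
            calls.append(
                RawCall(config.sample_ids[i], sv,
                        GenomicInterval(chrom, start, start + width), cn, p, q0)
            )
    return calls


def simulate_proteins(truth: GenotypeTruth, config: SimConfig) -> CohortTables:
    """Protein traits with planted CN effects plus covariate structure.

    protein = sum(beta x CN) + PC loadings + age/sex/batch terms +
    Normal(0, protein_noise_sd); a configured fraction of measurements is
    set missing at random.
    """
    rng = _rng(config, "proteins")
    region_idx = {r.region_id: j for j, r in enumerate(config.regions)}
    protein_idx = {p: j for j, p in enumerate(config.protein_ids)}
    for eff in config.effects:
        if eff.region_id not in region_idx:
            raise ValueError(f"effect references unknown region {eff.region_id}")
        if eff.protein_id not in protein_idx:
            raise ValueError(f"effect references unknown protein {eff.protein_id}")
    n, P = config.n_samples, config.n_proteins
    age = rng.uniform(30, 75, size=n).round(1)
    sex = rng.integers(0, 2, size=n)
    batch = rng.integers(0, config.n_batches, size=n)
    pcs = rng.normal(size=(n, config.n_pcs))
    pc_load = rng.normal(0.0, config.pc_effect_sd, size=(config.n_pcs, P))
    age_coef = rng.normal(0.0, config.age_effect_sd, size=P)
    sex_coef = rng.normal(0.0, config.sex_effect_sd, size=P)
    batch_eff = rng.normal(0.0, config.batch_effect_sd, size=(config.n_batches, P))
    y = pcs @ pc_load
    y += age[:, None] * age_coef[None, :]
    y += sex[:, None] * sex_coef[None, :]
    y += batch_eff[batch, :]
    for eff in config.effects:
        y[:, protein_idx[eff.protein_id]] += eff.beta * truth.cn[:, region_idx[eff.region_id]]
    y += rng.normal(0.0, config.protein_noise_sd, size=(n, P))
    if config.protein_missing_rate > 0:
        y[rng.random(size=(n, P)) < config.protein_missing_rate] = np.nan
    sids = config.sample_ids
    proteins = pd.DataFrame(y, index=sids, columns=config.protein_ids)
    covariates = pd.DataFrame({"age": age, "sex": sex, "batch": batch}, index=sids)
    pcs_df = pd.DataFrame(pcs, index=sids, columns=[f"PC{k+1}" for k in range(config.n_pcs)])
    return CohortTables(proteins=proteins, covariates=covariates, pcs=pcs_df)


def _flip_prob_for_r2(target_r2: float, carrier_freq: float) -> float:
    """Flip probability so the binary carrier-copy SNP attains the target R^2.

    For binary vectors the Spearman and Pearson correlations coincide; with
    carrier frequency p and flip probability f the correlation is
    ``p(1-p)(1-2f) / sqrt(p(1-p) q(1-q))`` with ``q = p(1-f) + (1-p)f``.
    """
    if not (0 < carrier_freq < 1):
        raise ValueError("carrier frequency must be in (0,1) to target LD")
    if target_r2 >= 1.0:
        return 0.0
    p = carrier_freq

    def rho2(f: float) -> float:
        q = p * (1 - f) + (1 - p) * f
        if q <= 0 or q >= 1:
            return 0.0
        rho = p * (1 - p) * (1 - 2 * f) / np.sqrt(p * (1 - p) * q * (1 - q))
        return rho * rho

    if target_r2 <= 0.0:
        return 0.5
    return float(optimize.brentq(lambda f: rho2(f) - target_r2, 0.0, 0.5, xtol=1e-10))


def simulate_snps(
    truth: GenotypeTruth, config: SimConfig
) -> tuple[pd.DataFrame, dict[str, tuple[str, int]]]:
    """SNP allele counts in controlled LD with CNV carrier status.

    Each targeted region gets one biallelic SNP built by copying the
    region's carrier indicator with a flip probability solved from the
    closed-form binary correlation, so the realized Spearman R^2 is close
    to the target. Returns the samples x SNPs matrix and SNP positions
    (placed 10 kbp downstream of the region).
    """
    rng = _rng(config, "snps")
    cols: dict[str, np.ndarray] = {}
    positions: dict[str, tuple[str, int]] = {}
    for region_id, target in config.snp_ld_targets.items():
        j = [k for k, r in enumerate(config.regions) if r.region_id == region_id]
        if not j:
            raise ValueError(f"snp_ld_targets references unknown region {region_id}")
        j = j[0]
        reg = config.regions[j]
        carrier = (truth.dosage[:, j] > 0).astype(float)
        p_hat = carrier.mean()
        f = _flip_prob_for_r2(target, p_hat)
        flips = rng.random(config.n_samples) < f
        snp = np.where(flips, 1.0 - carrier, carrier)
        snp_id = f"snp_{region_id}"
        cols[snp_id] = snp
        L = config.chromosome_lengths[reg.interval.chrom]
        positions[snp_id] = (reg.interval.chrom, min(reg.interval.end + 10_000, L - 1))
    return pd.DataFrame(cols, index=config.sample_ids), positions


def simulate_longread_calls(
    truth: GenotypeTruth,
    config: SimConfig,
    sample_indices: list[int] | None = None,
) -> tuple[dict[str, list[SVRecord]], dict[str, float]]:
    """Long-read SV call sets with SV-type-dependent sensitivity.

    Each true carrier event is emitted with probability
    ``longread_sensitivity[sv_type]``; breakpoints are re-jittered with the
    (smaller) long-read jitter SD. A configured fraction of samples gets a
    molecular yield below 30 Gbp to exercise the coverage QC; duplications
    can be emitted as clusters of small insertions instead of one DUP.
    """
    rng = _rng(config, "longread")
    if sample_indices is None:
        sample_indices = list(range(config.n_samples))
    sids = config.sample_ids
    records: dict[str, list[SVRecord]] = {sids[i]: [] for i in sample_indices}
    yields: dict[str, float] = {}
    for i in sample_indices:
        if rng.random() < config.longread_low_yield_fraction:
            yields[sids[i]] = float(rng.uniform(10.0, 29.9))
        else:
            yields[sids[i]] = float(config.longread_yield_gbp + rng.normal(0.0, 3.0))
    for i in sample_indices:
        for j, reg in enumerate(config.regions):
            if truth.dosage[i, j] == 0:
                continue
            if rng.random() >= config.longread_sensitivity.get(reg.sv_type, 0.0):
                continue
            base = truth.realized[(i, j)]
            ds, de = np.round(rng.normal(0, config.longread_jitter_sd, size=2)).astype(int)
            L = config.chromosome_lengths[base.chrom]
            s = max(0, base.start + int(ds))
            e = min(L, base.end + int(de))
            if e <= s:
                s, e = base.start, base.end
            gt = Genotype.HOM_ALT if truth.dosage[i, j] == 2 else Genotype.HET
            if reg.sv_type == "deletion":
                records[sids[i]].append(
                    SVRecord(sids[i], SVType.DEL, GenomicInterval(base.chrom, s, e), gt, "sim")
                )
            elif rng.random() < config.dup_as_ins_fraction:
                for pos in np.sort(rng.integers(s, e, size=int(rng.integers(2, 5)))):
                    records[sids[i]].append(
                        SVRecord(sids[i], SVType.INS,
                                 GenomicInterval(base.chrom, int(pos), int(pos) + 1), gt, "sim")
                    )
            else:
                records[sids[i]].append(
                    SVRecord(sids[i], SVType.DUP, GenomicInterval(base.chrom, s, e), gt, "sim")
                )
    return records, yields


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_sim_config(seed: int = 0, n_samples: int = 500, n_regions: int = 30,
                       n_proteins: int = 20) -> SimConfig:
    """The default synthetic cohort: 500 samples, 30 CNV regions over three
    chromosomes, 20 proteins, two planted effects of |beta| = 0.8 on
    regions with allele frequency >= 0.1."""
    rng = np.random.default_rng([seed, 7])
    chroms = {"1": 1_200_000, "2": 1_200_000, "3": 1_200_000}
    chrom_names = list(chroms)
    regions: list[TruthRegion] = []
    spacing = (len(chrom_names) * 1_200_000 - 100_000) // n_regions
    for k in range(n_regions):
        pos = 50_000 + k * spacing
        chrom = chrom_names[pos // 1_200_000]
        start = pos % 1_200_000
        width = int(rng.integers(10, 41)) * 200  # 2-8 kbp
        af = float(rng.uniform(0.1, 0.4))
        sv = "deletion" if rng.random() < 0.5 else "duplication"
        regions.append(
            TruthRegion(f"R{k:02d}", GenomicInterval(chrom, start, start + width), sv, af)
        )
    effects = [
        EffectSpec("R00", "P000", 0.8),
        EffectSpec("R05", "P001", -0.8),
    ]
    return SimConfig(
        n_samples=n_samples,
        chromosome_lengths=chroms,
        regions=regions,
        effects=effects,
        n_proteins=n_proteins,
        seed=seed,
    )


def null_sim_config(seed: int = 0, n_samples: int = 300, n_regions: int = 50,
                    n_proteins: int = 200) -> SimConfig:
    """A cohort with no planted effects for calibration of the association
    null: 50 clean CNV regions (no jitter, no spurious calls) x 200
    proteins gives 10,000 association tests whose p-values should be
    uniform."""
    cfg = default_sim_config(seed=seed, n_samples=n_samples, n_regions=n_regions,
                             n_proteins=n_proteins)
    regions = [
        TruthRegion(r.region_id, r.interval, r.sv_type, r.allele_frequency,
                    r.cn_per_allele, breakpoint_jitter_sd=0)
        for r in cfg.regions
    ]
    cfg.regions = regions
    cfg.effects = []
    cfg.false_calls_per_sample = 0.0
    cfg.q0_fail_rate = 0.0
    cfg.protein_missing_rate = 0.0
    return cfg


def validation_sim_config(seed: int = 0, n_samples: int = 15,
                          n_regions_per_type: int = 800) -> SimConfig:
    """A long-read validation cohort mirroring a small resequencing panel.

    A resequencing-panel-sized subcohort (15 samples, a fifth failing the 30-Gbp yield
    screen) over many rare CNV regions (AF 0.02, half deletions, half
    duplications, no breakpoint jitter so each region genotypes as one
    merged unit). Long-read sensitivity defaults reproduce the qualitative
    asymmetry between deletions and duplications (0.95 vs 0.05).
    """
    rng = np.random.default_rng([seed, 8])
    n_chroms = 4
    per_chrom = (2 * n_regions_per_type + n_chroms - 1) // n_chroms
    spacing = 4200
    chrom_len = per_chrom * spacing + 10_000
    chroms = {str(c + 1): chrom_len for c in range(n_chroms)}
    regions: list[TruthRegion] = []
    types = ["deletion", "duplication"] * n_regions_per_type
    for k in range(2 * n_regions_per_type):
        chrom = str(k // per_chrom + 1)
        start = 5_000 + (k % per_chrom) * spacing
        width = int(rng.integers(5, 14)) * 200  # 1-2.6 kbp
        regions.append(
            TruthRegion(f"V{k:04d}", GenomicInterval(chrom, start, start + width),
                        types[k], allele_frequency=0.02, breakpoint_jitter_sd=0)
        )
    return SimConfig(
        n_samples=n_samples,
        chromosome_lengths=chroms,
        regions=regions,
        seed=seed,
        n_proteins=2,
        false_calls_per_sample=0.0,
        q0_fail_rate=0.0,
        longread_sensitivity={"deletion": 0.95, "duplication": 0.05},
        longread_low_yield_fraction=0.2,
    )
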