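# Methods

This note documents the statistical procedures implemented in `cnvpqtl`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about behavior on real data.

## Read-depth calling (`rd_caller`)

The signal is per-bp read depth summed into bins. Bin size is chosen per
sample as the smallest candidate from (70, 85, 100, 150, 200, 250) bp
whose binned mean/SD ratio falls in [4, 5], bounds inclusive — the
inclusive choice is ours; the rule itself only says "between". The ratio
band balances t-test power against breakpoint resolution. For pure Poisson
depth the ratio is sqrt(b·λ) exactly, which the unit tests exploit as a
closed-form oracle; it also means that at 30× a Poisson profile exceeds
the band at every candidate (real depth signal is overdispersed), so the
caller exposes a `force_largest` fallback and callers may fix the bin size
directly.

Per-call statistics:

* copy number `cn = 2 · mean(regional bins) / global mean` — scale
  invariant by construction; the global mean is computed per chromosome
  (depth normalization is naturally per-chromosome; a genome-wide mean
  would leak inter-chromosome coverage differences into CN);
* a two-sided one-sample t-test of regional bin depths against the global
  mean, with the degenerate zero-SD case mapped to p = 0 (mean differs) or
  p = 1 (mean equal) — a documented convention, clamped into (0, 1] when a
  call record is emitted;
* q0 = depth-weighted mean of per-bin ambiguous-alignment fractions, 0
  when the region has zero depth.

Segmentation is a deliberately simple substitute for mean-shift
partitioning: maximal runs of ≥ 5 bins with depth ratio < 0.75 (deletion)
or > 1.25 (duplication) and ≥ 1000 bp. The thresholds are plumbing, are
exposed in `SegmentationParams`, and are tuned for nothing beyond feeding
the matrix stage; the 1000-bp floor mirrors the smallest calls the
pipeline is meant to handle.

## Population CN matrix (`cnv_matrix`)

Strict tier: a call is high-confidence iff `p < alpha / (n_samples × m_s)`
(`m_s` = calls in its own sample) and `q0 < 0.5`. Lenient tier: q0 only.
Windows are a fixed 200-bp tiling; terminal truncated windows participate
normally. Cell resolution when several lenient calls overlap one window
for one sample: largest bp overlap wins, ties to the smaller call start —
a deterministic rule chosen because the data cannot distinguish the
candidates. Merging uses exact equality of stored CN values (missing
matches only missing): CN values in adjacent windows originate from the
same call object and are bit-identical, while tolerance-based merging
would make unit counts depend on the tolerance.

## Association (`association`)

Order of operations: proteins are first residualized on age + sex + batch
(OLS, batch categorical, singular terms dropped with a warning), then
rank-based inverse-normal transformed with the Blom offset 3/8 and
standardized with the n−1 SD so the output moments are exactly 0/1. The
offset choice is conventional; any offset followed by standardization
yields nearly identical z-scores at cohort sizes. Genetic PCs enter the
association model itself, not the pre-residualization.

A (CNV, protein) pair is testable iff ≥ 3 samples have CN ≠ 2 (tolerance
1e-9: wild-type fill is exactly 2.0, while genotyped CN near 2 still
counts as carrying) and a protein value. The model is OLS of the
normalized protein on intercept + CN + first 4 PCs (10 in the sensitivity
setting), listwise deletion, two-sided t on the CN coefficient. The
family-wise threshold is exactly 0.05 divided by the number of tests
actually performed. Inflation is the median of chi-square(1) quantiles of
the p-values over 0.45494; group comparison of per-protein lambdas uses
Kruskal–Wallis. Cis/trans: cis iff the CNV and the protein's coding gene
are on one chromosome less than 2 Mbp apart; enrichment uses the
two-sided Fisher exact test (point-probability definition of
two-sidedness).

## Clumping and conditioning (`clump_ld`)

LD between CN vectors (and between CN and SNP allele counts) is the
squared Spearman rank correlation — rank-based because CN distributions
are mixtures of a point mass at 2 and carrier values. Clumping is greedy
by smallest p (ties: smaller start): the lead absorbs same-chromosome,
same-protein units with R² > 0.8; units with R² < 0.1 to every lead are
independent. The dead zone 0.1 ≤ R² ≤ 0.8 is not silently assigned:
such units seed their own clumps flagged `correlated_unresolved` with the
nearest offending lead named, so downstream counts can include or exclude
them explicitly. Conditional fits add SNP allele counts as covariates and
error on in-sample collinearity (R² = 1) rather than returning an
arbitrary coefficient.

## Long-read concordance (`longread_concord`)

Yield QC: pass iff ≥ 30 Gbp (≈ 10× long-read coverage). Equivalence:
50% reciprocal overlap plus a consistent CN direction; the secondary 1-bp
mode recovers duplications that long-read callers report as clusters of
small insertions (INS counts as duplication-consistent by default,
switchable). INV and BND never count. A (CNV, sample) pair is
not-assessable when the sample failed yield QC or regional coverage is
below 5× — the regional threshold is our number, configurable, since only
the existence of a regional criterion is given. Concordance is
CN-direction agreement only (zygosity is not required). Summaries count
carriers per CNV; `validated_100` requires zero discordant carriers and at
least one assessed carrier, and per-CNV fractions are reported over CNVs
with an assessed carrier (the flag is undefined otherwise).

## Synthetic cohorts (`synthetic_data`)

The generator emulates: Hardy–Weinberg CNV genotypes with per-sample
breakpoint jitter (shared by both alleles — allele phase is unobservable
in depth data); per-bp Poisson depth scaled by CN/2 with injectable q0
mass; proteins as linear CN effects + PC/age/sex/batch structure +
Gaussian noise; SNPs copying the carrier indicator with a flip probability
solved in closed form from the binary correlation so realized Spearman R²
hits a target; long-read call sets with per-carrier-event sensitivity by
SV type and per-sample yields. All generators are pure functions of
(config, seed), via per-operation RNG streams.

It does **not** model GC bias, mappability structure beyond q0, genotyping
batch effects, protein detection limits, relatedness/kinship, or
realistic LD beyond the single engineered SNP per region — so passing
tests demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data artifacts.

Default study conditions, chosen once: 500 samples, 30 regions (2–8 kbp,
AF 0.1–0.4, jitter SD 100 bp) on three 1.2-Mbp chromosomes, 20 proteins,
two planted effects of ±0.8 per CN unit, 30× depth, ~1 spurious call per
sample, 2% of calls given failing q0. End-to-end runs generate call
tables directly from truth (CN + N(0, 0.05) noise; p from the Poisson
depth model's expected t statistic) so a 20-seed sweep takes about a
minute; the depth→caller route is exercised separately at single-sample
scale. Two derived condition sets: a null cohort (300 samples, 50 clean
regions × 200 proteins = 10,000 tests, no effects) for calibration, and a
validation cohort (15 samples, 20% failing yield QC, 1600 rare regions at
AF 0.02 without jitter, long-read sensitivity 0.95 del / 0.05 dup) for the
concordance asymmetry. In the validation setting the probability that a
deletion CNV with k assessed carriers validates to 100% is 0.95^k, so rare
regions (k mostly 1–2) and many regions are used to estimate the fraction
stably.

Recovery accounting: a significant clump is attributed to a planted
(region, protein) effect when its span lies within 4 jitter SDs of the
truth interval — carrier breakpoints scatter around the truth, so
significant edge windows can abut the interval without overlapping it;
they are signal, not false positives.

## Numerical notes

* p-values are clamped into (0, 1] at the floating-point floor; OLS uses
  `lstsq` with an explicit rank check.
* Coordinates are 0-based half-open in memory; the caller TSV dialect and
  VCF are 1-based at the file boundary. When a VCF SV record lacks an
  explicit END, the span is recovered as |SVLEN| from POS (htslib's
  padding-base interpretation is normalized away).
* Merged-unit columns compare with NaN-aware exact equality; clump tie
  breaks and window tie breaks are fully deterministic, so every pipeline
  output is a pure function of (input, config).

## Known limitations

The segmenter is not a mean-shift partitioner and will fragment complex
nested events; sex chromosomes are treated as diploid; multi-caller
long-read consensus is out of scope (one call set at a time); the
cis/trans labeller needs gene coordinates supplied by the user; and the
simulator's LD engineering supports one SNP per region.
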