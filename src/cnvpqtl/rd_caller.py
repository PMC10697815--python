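"""A simplified read-depth CNV caller.

Implements the depth-signal bin-size selection rule (smallest candidate
bin for which the binned read-depth mean/SD ratio falls in [4, 5]) and the
per-call statistics: a real-valued copy number from the regional/global
depth ratio, a two-sided one-sample t-test of regional bin depths against
the global mean, and a depth-weighted q0 fraction.

Segmentation is a deliberately simple threshold-run substitute for
mean-shift partitioning: maximal runs of consecutive bins whose depth ratio
to the chromosome mean is below 0.75 (deletion) or above 1.25 (duplication),
at least 5 bins and 1000 bp long. The thresholds are exposed in
:class:`SegmentationParams`; the intent is a caller good enough to feed the
genotyping matrix, not a CNVnator replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GenomicInterval, RawCall

DEFAULT_BIN_CANDIDATES = (70, 85, 100, 150, 200, 250)


class BinSizeError(ValueError):
    """No candidate bin size reached the target mean/SD ratio band."""

    def __init__(self, ratios: dict[int, float], lo: float, hi: float):
        self.ratios = ratios
        pretty = ", ".join(f"{b}: {r:.3f}" for b, r in ratios.items())
        super().__init__(
            f"no candidate bin size with mean/SD ratio in [{lo}, {hi}]; ratios: {pretty}"
        )


def bin_depth(per_bp_depth: np.ndarray, bin_size: int) -> np.ndarray:
    """Sum per-bp depth into consecutive bins; a trailing partial bin is dropped."""
    n = len(per_bp_depth) // bin_size
    if n == 0:
        raise ValueError("depth vector shorter than one bin")
    return np.asarray(per_bp_depth[: n * bin_size], dtype=float).reshape(n, bin_size).sum(axis=1)


def select_bin_size(
    per_bp_depth: np.ndarray,
    candidates: tuple[int, ...] = DEFAULT_BIN_CANDIDATES,
    ratio_low: float = 4.0,
    ratio_high: float = 5.0,
    force_largest: bool = False,
) -> tuple[int, dict[int, float]]:
    """Pick the smallest candidate bin size with binned mean/SD in the target band.

    The band is inclusive on both ends. Returns ``(chosen, ratios)`` where
    ``ratios`` records the mean/SD ratio per candidate. When no candidate
    qualifies, raises :class:`BinSizeError` carrying all ratios, unless
    ``force_largest`` is set, in which case the largest candidate is returned.
    """
    per_bp_depth = np.asarray(per_bp_depth, dtype=float)
    if len(per_bp_depth) < max(candidates) * 100:
        raise ValueError("depth vector too short for stable bin statistics")
    ratios: dict[int, float] = {}
    chosen: int | None = None
    for b in sorted(candidates):
        binned = bin_depth(per_bp_depth, b)
        sd = binned.std(ddof=1)
        ratios[b] = np.inf if sd == 0 else binned.mean() / sd
        if chosen is None and ratio_low <= ratios[b] <= ratio_high:
            chosen = b
    if chosen is None:
        if force_largest:
            return max(candidates), ratios
        raise BinSizeError(ratios, ratio_low, ratio_high)
    return chosen, ratios


def estimate_cn(regional_bins: np.ndarray, global_mean: float) -> float:
    """Copy number as twice the regional-to-global mean depth ratio.

    Scale-invariant: multiplying all depths by a positive constant leaves
    the estimate unchanged.
    """
    regional_bins = np.asarray(regional_bins, dtype=float)
    if regional_bins.size == 0:
        raise ValueError("empty region")
    if global_mean <= 0:
        raise ValueError("global mean depth must be positive")
    return 2.0 * regional_bins.mean() / global_mean


def call_significance(regional_bins: np.ndarray, global_mean: float) -> float:
    """Two-sided one-sample t-test of regional bin depths against the global mean.

    With zero regional SD the t statistic is undefined; by convention the
    p-value is 0 when the regional mean differs from the global mean and 1
    when it equals it.
    """
    regional_bins = np.asarray(regional_bins, dtype=float)
    if regional_bins.size < 2:
        raise ValueError("need at least 2 regional bins for a t-test")
    sd = regional_bins.std(ddof=1)
    if sd == 0:
        return 1.0 if regional_bins.mean() == global_mean else 0.0
    t = (regional_bins.mean() - global_mean) / (sd / np.sqrt(regional_bins.size))
    p = 2.0 * stats.t.sf(abs(t), df=regional_bins.size - 1)
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def compute_q0(q0_per_bin: np.ndarray, bin_depths: np.ndarray) -> float:
    """Depth-weighted mean of per-bin q0 fractions; 0 when total depth is 0."""
    q0_per_bin = np.asarray(q0_per_bin, dtype=float)
    bin_depths = np.asarray(bin_depths, dtype=float)
    if q0_per_bin.size == 0 or q0_per_bin.shape != bin_depths.shape:
        raise ValueError("q0 and depth vectors must be non-empty and aligned")
    total = bin_depths.sum()
    if total == 0:
        return 0.0
    return float((q0_per_bin * bin_depths).sum() / total)


@dataclass
class BinProfile:
    """Binned read-depth signal for one chromosome of one sample."""

    chrom: str
    bin_size: int
    depths: np.ndarray
    q0_per_bin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise ValueError("negative bin depth")
        if self.q0_per_bin is None:
            self.q0_per_bin = np.zeros_like(self.depths)
        else:
            self.q0_per_bin = np.asarray(self.q0_per_bin, dtype=float)
        if self.q0_per_bin.shape != self.depths.shape:
            raise ValueError("q0_per_bin misaligned with depths")


@dataclass(frozen=True)
class SegmentationParams:
    del_ratio: float = 0.75
    dup_ratio: float = 1.25
    min_bins: int = 5
    min_width_bp: int = 1000


def segment(
    profile: BinProfile,
    sample_id: str,
    params: SegmentationParams = SegmentationParams(),
) -> list[RawCall]:
    """Call CNVs as threshold runs on a binned depth profile.

    Maximal runs of >= ``min_bins`` consecutive bins with depth below
    ``del_ratio`` (or above ``dup_ratio``) times the chromosome mean become
    calls, provided they span >= ``min_width_bp``. Each call is annotated
    with :func:`estimate_cn`, :func:`call_significance` and
    :func:`compute_q0`. The chromosome mean is the global reference —
    per-chromosome normalization mirrors depth normalization per chromosome.
    """
    depths = profile.depths
    global_mean = depths.mean()
    if global_mean == 0:
        return []
    ratio = depths / global_mean
    state = np.zeros(len(ratio), dtype=np.int8)
    state[ratio < params.del_ratio] = -1
    state[ratio > params.dup_ratio] = 1
    calls: list[RawCall] = []
    boundaries = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(state)]))
    for s, e in zip(starts, ends):
        if state[s] == 0 or e - s < params.min_bins:
            continue
        width = (e - s) * profile.bin_size
        if width < params.min_width_bp:
            continue
        region = depths[s:e]
        cn = estimate_cn(region, global_mean)
        sv_type = "deletion" if state[s] < 0 else "duplication"
        calls.append(
            RawCall(
                sample_id=sample_id,
                sv_type=sv_type,
                interval=GenomicInterval(
                    profile.chrom, s * profile.bin_size, e * profile.bin_size
                ),
                cn=cn,
                # zero-SD regions (e.g. hom deletions) get the p=0 convention;
                # clamp into (0,1] for the call record
                p_value=max(call_significance(region, global_mean),
                            np.nextafter(0.0, 1.0)),
                q0=compute_q0(profile.q0_per_bin[s:e], region),
            )
        )
    return calls


def call_sample(
    per_bp_depth: dict[str, np.ndarray],
    sample_id: str,
    candidates: tuple[int, ...] = DEFAULT_BIN_CANDIDATES,
    params: SegmentationParams = SegmentationParams(),
    q0_per_bp: dict[str, np.ndarray] | None = None,
    force_largest: bool = False,
) -> list[RawCall]:
    """Bin-size selection + segmentation over all chromosomes of one sample.

    Bin size is selected once per sample from the concatenated depth signal,
    then segmentation runs per chromosome (per-chromosome global mean).
    """
    concat = np.concatenate(list(per_bp_depth.values()))
    bin_size, _ = select_bin_size(concat, candidates, force_largest=force_largest)
    calls: list[RawCall] = []
    for chrom, depth in per_bp_depth.items():
        binned = bin_depth(depth, bin_size)
        if q0_per_bp is not None and chrom in q0_per_bp:
            n = len(binned)
            q0_bins = (
                np.asarray(q0_per_bp[chrom][: n * bin_size], dtype=float)
                .reshape(n, bin_size)
                .mean(axis=1)
            )
        else:
            q0_bins = None
        profile = BinProfile(chrom, bin_size, binned, q0_bins)
        calls.extend(segment(profile, sample_id, params))
    return calls
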