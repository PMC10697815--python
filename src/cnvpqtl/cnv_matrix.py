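"""Two-tier QC and construction of the population copy-number matrix.

Discovery calls pass a strict tier (per-sample Bonferroni on the t-test
p-value, over ``n_samples x calls-in-sample`` tests, plus a q0 cutoff) to
nominate 200-bp genome windows. Genotyping then applies a lenient tier —
the q0 cutoff only — to fill each (sample, window) cell: the overlapping
call's real-valued CN, exactly 2.0 for wild type, or missing where the
sample's only overlapping calls failed QC. Adjacent windows whose CN
columns are identical across all samples (missing matching missing) are
merged; the merged units are the substrate for association testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, RawCall
from .io_formats import format_region

# provenance codes
WILDTYPE_FILL = 0
CALLED = 1
FAILED_QC = 2


@dataclass(frozen=True)
class QCThresholds:
    """Strict-tier family-wise alpha and the q0 retention bound (exclusive)."""

    alpha: float = 0.05
    q0_max: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if not (0 < self.q0_max <= 1):
            raise ValueError("q0_max must be in (0,1]")


@dataclass
class WindowGrid:
    """Non-overlapping tiling of each chromosome into fixed-size windows."""

    window_size: int
    chromosome_lengths: Mapping[str, int]
    windows: list[GenomicInterval]


@dataclass
class CNMatrix:
    """Samples x selected-windows matrix of real CN values with provenance."""

    sample_ids: list[str]
    windows: list[GenomicInterval]
    values: np.ndarray  # (n_samples, n_windows), NaN = missing
    provenance: np.ndarray  # same shape, int8 codes

    def to_frame(self) -> pd.DataFrame:
        """Rows = windows (``chrom:start-end``, 1-based), columns = samples."""
        return pd.DataFrame(
            self.values.T,
            index=[format_region(w) for w in self.windows],
            columns=self.sample_ids,
        )


@dataclass
class MergedCNV:
    """Maximal run of adjacent windows with identical CN columns."""

    interval: GenomicInterval
    member_windows: list[GenomicInterval]
    column_signature: np.ndarray  # per-sample CN, NaN = missing

    @property
    def region(self) -> str:
        return format_region(self.interval)


def qc_high_confidence(
    calls: Iterable[RawCall], n_samples: int, thresholds: QCThresholds = QCThresholds()
) -> list[RawCall]:
    """Strict tier: p < alpha / (n_samples x m_s) and q0 < q0_max.

    ``m_s`` is the number of calls in the call's own sample, so the
    Bonferroni correction is for the number of samples and the number of
    CNVs identified in each respective sample.
    """
    calls = list(calls)
    m_per_sample: dict[str, int] = {}
    for c in calls:
        m_per_sample[c.sample_id] = m_per_sample.get(c.sample_id, 0) + 1
    kept = []
    for c in calls:
        cutoff = thresholds.alpha / (n_samples * m_per_sample[c.sample_id])
        if c.p_value < cutoff and c.q0 < thresholds.q0_max:
            kept.append(c)
    return kept


def lenient_filter(calls: Iterable[RawCall], thresholds: QCThresholds = QCThresholds()):
    """Lenient genotyping tier: only the q0 threshold applied."""
    return [c for c in calls if c.q0 < thresholds.q0_max]


def build_window_grid(
    chromosome_lengths: Mapping[str, int], window_size: int = 200
) -> WindowGrid:
    """Tile each chromosome into ``window_size``-bp windows, truncating the last."""
    windows: list[GenomicInterval] = []
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom}")
        for start in range(0, length, window_size):
            windows.append(GenomicInterval(chrom, start, min(start + window_size, length)))
    return WindowGrid(window_size, dict(chromosome_lengths), windows)


def _overlapping_window_idx(
    iv: GenomicInterval,
    chrom_starts: Mapping[str, np.ndarray],
    chrom_ends: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Indices (into the per-chromosome window arrays) overlapped by >= 1 bp."""
    if iv.chrom not in chrom_starts:
        return np.empty(0, dtype=int)
    starts = chrom_starts[iv.chrom]
    ends = chrom_ends[iv.chrom]
    lo = np.searchsorted(ends, iv.start, side="right")
    hi = np.searchsorted(starts, iv.end, side="left")
    return np.arange(lo, hi)


def _index_windows(windows: Sequence[GenomicInterval]):
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    chrom_starts = {c: np.array([windows[i].start for i in idx]) for c, idx in by_chrom.items()}
    chrom_ends = {c: np.array([windows[i].end for i in idx]) for c, idx in by_chrom.items()}
    chrom_global = {c: np.array(idx) for c, idx in by_chrom.items()}
    return chrom_starts, chrom_ends, chrom_global


def select_windows(
    high_confidence_calls: Iterable[RawCall], grid: WindowGrid
) -> list[GenomicInterval]:
    """Windows overlapped by >= 1 bp by any high-confidence call, in (chrom, start) order."""
    chrom_starts, chrom_ends, chrom_global = _index_windows(grid.windows)
    selected: set[int] = set()
    for call in high_confidence_calls:
        local = _overlapping_window_idx(call.interval, chrom_starts, chrom_ends)
        selected.update(chrom_global[call.interval.chrom][local].tolist())
    return [grid.windows[i] for i in sorted(selected)]


def genotype_windows(
    all_calls: Iterable[RawCall],
    selected_windows: Sequence[GenomicInterval],
    sample_ids: Sequence[str],
    thresholds: QCThresholds = QCThresholds(),
) -> CNMatrix:
    """Fill the samples x windows CN matrix from the lenient call tier.

    Per (sample, window): the CN of the overlapping lenient call (largest
    bp overlap wins, ties broken by smaller call start); missing when the
    sample's only overlapping calls failed the q0 threshold; otherwise the
    wild-type fill of exactly 2.0.
    """
    sample_ids = list(sample_ids)
    sample_idx = {s: i for i, s in enumerate(sample_ids)}
    n_s, n_w = len(sample_ids), len(selected_windows)
    values = np.full((n_s, n_w), 2.0)
    provenance = np.full((n_s, n_w), WILDTYPE_FILL, dtype=np.int8)
    # best (overlap_bp, -start) candidate per cell
    best_key = np.full((n_s, n_w, 2), -np.inf)

    chrom_starts, chrom_ends, chrom_global = _index_windows(selected_windows)
    win_start = np.array([w.start for w in selected_windows])
    win_end = np.array([w.end for w in selected_windows])

    for call in all_calls:
        if call.sample_id not in sample_idx:
            continue
        si = sample_idx[call.sample_id]
        local = _overlapping_window_idx(call.interval, chrom_starts, chrom_ends)
        if local.size == 0:
            continue
        cols = chrom_global[call.interval.chrom][local]
        passes = call.q0 < thresholds.q0_max
        if not passes:
            # mark failed-QC overlap; only downgrades cells with no lenient call
            mask = provenance[si, cols] == WILDTYPE_FILL
            provenance[si, cols[mask]] = FAILED_QC
            values[si, cols[mask]] = np.nan
            continue
        ov = np.minimum(win_end[cols], call.interval.end) - np.maximum(
            win_start[cols], call.interval.start
        )
        for col, o in zip(cols, ov):
            key = (float(o), -float(call.interval.start))
            if key > tuple(best_key[si, col]):
                best_key[si, col] = key
                values[si, col] = call.cn
                provenance[si, col] = CALLED
    return CNMatrix(sample_ids, list(selected_windows), values, provenance)


def _columns_identical(a: np.ndarray, b: np.ndarray) -> bool:
    both_nan = np.isnan(a) & np.isnan(b)
    return bool(np.all(both_nan | (a == b)))


def merge_adjacent(matrix: CNMatrix) -> list[MergedCNV]:
    """Merge maximal runs of grid-adjacent windows with identical CN columns.

    Adjacency requires the same chromosome and the next window starting
    exactly where the previous ends; windows separated by an unselected
    window never merge. Missing entries match only missing entries.
    Idempotent: merging the merged units again is the identity.
    """
    merged: list[MergedCNV] = []
    run: list[int] = []

    def flush() -> None:
        if not run:
            return
        ws = [matrix.windows[i] for i in run]
        merged.append(
            MergedCNV(
                interval=GenomicInterval(ws[0].chrom, ws[0].start, ws[-1].end),
                member_windows=ws,
                column_signature=matrix.values[:, run[0]].copy(),
            )
        )
        run.clear()

    order = sorted(range(len(matrix.windows)),
                   key=lambda i: (matrix.windows[i].chrom, matrix.windows[i].start))
    for i in order:
        if run:
            prev = matrix.windows[run[-1]]
            cur = matrix.windows[i]
            adjacent = prev.chrom == cur.chrom and prev.end == cur.start
            if not (adjacent and _columns_identical(matrix.values[:, run[-1]],
                                                    matrix.values[:, i])):
                flush()
        run.append(i)
    flush()
    return merged


def merged_to_frame(merged: Sequence[MergedCNV], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Merged CNVs as a rows-by-samples DataFrame (the association substrate)."""
    return pd.DataFrame(
        np.array([m.column_signature for m in merged]).reshape(len(merged), -1),
        index=[m.region for m in merged],
        columns=list(sample_ids),
    )
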