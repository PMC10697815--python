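"""Validation of short-read CNV calls against long-read SV call sets.

Samples are first screened on unique molecular yield (>= 30 Gbp, i.e. about
10x long-read coverage). A short-read CNV and a long-read SV are equivalent
when they share 50% reciprocal overlap and imply a consistent copy-number
direction (deletion <-> DEL; duplication <-> DUP, or insertion clusters if
enabled); a secondary mode relaxes the overlap requirement to 1 bp. Each
(CNV, sample) pair is then classified concordant / discordant /
not-assessable, and per-CNV summaries report carrier counts and the
classification tallies with a 100%-validated flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, SVRecord, SVType

YIELD_MIN_GBP = 30.0


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    yield_gbp: float
    passed: bool


@dataclass
class ConcordanceRecord:
    cnv_id: str
    sample_id: str
    short_state: str  # deletion | duplication | wildtype | missing
    long_state: str  # deletion | duplication | none | low_coverage
    classification: str  # concordant | discordant | not_assessable
    sample_passed: bool = True


def coverage_qc(yields_gbp: Mapping[str, float], yield_min: float = YIELD_MIN_GBP) -> list[SampleQC]:
    """Yield screen: a sample passes iff its molecular yield is >= 30 Gbp."""
    out = []
    for sid, y in yields_gbp.items():
        if y < 0:
            raise ValueError(f"negative yield for {sid}")
        out.append(SampleQC(sid, float(y), bool(y >= yield_min)))
    return out


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/|a|, overlap/|b|); 0 across chromosomes."""
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    return min(ov / a.width, ov / b.width)


def _direction_consistent(short_type: str, sv: SVType, ins_as_dup: bool = True) -> bool:
    if sv in (SVType.INV, SVType.BND):
        return False
    if short_type == "deletion":
        return sv is SVType.DEL
    if short_type == "duplication":
        return sv is SVType.DUP or (ins_as_dup and sv is SVType.INS)
    return False


def match_calls(
    short_interval: GenomicInterval,
    short_type: str,
    long_records: Iterable[SVRecord],
    mode: str = "reciprocal_50",
    ins_as_dup: bool = True,
) -> list[SVRecord]:
    """Long-read records equivalent to a short-read CNV.

    ``reciprocal_50``: >= 50% reciprocal overlap and consistent CN
    direction. ``any_1bp``: >= 1 bp overlap with the same direction rule —
    the mode in which duplication calls reported as clusters of small
    insertions can be recovered. INV and BND are never consistent.
    """
    if mode not in ("reciprocal_50", "any_1bp"):
        raise ValueError(f"unknown mode {mode!r}")
    matched = []
    for rec in long_records:
        if not _direction_consistent(short_type, rec.sv_type, ins_as_dup):
            continue
        if mode == "reciprocal_50":
            if reciprocal_overlap(short_interval, rec.interval) >= 0.5:
                matched.append(rec)
        else:
            if short_interval.overlap_bp(rec.interval) >= 1:
                matched.append(rec)
    return matched


def _short_state(cn: float) -> str:
    if np.isnan(cn):
        return "missing"
    if cn < 2:
        return "deletion"
    if cn > 2:
        return "duplication"
    return "wildtype"


def classify_concordance(
    cn_frame: pd.DataFrame,
    cnv_intervals: Mapping[str, GenomicInterval],
    records_by_sample: Mapping[str, Sequence[SVRecord]],
    sample_qc: Sequence[SampleQC],
    regional_coverage: Callable[[str, str], float] | float = 10.0,
    coverage_min: float = 5.0,
    mode: str = "reciprocal_50",
    ins_as_dup: bool = True,
) -> list[ConcordanceRecord]:
    """Classify every (CNV, sample) pair against the long-read call set.

    ``cn_frame``: CNV units (rows, region strings) x samples, real CN with
    NaN. ``regional_coverage`` gives the sample's long-read coverage over a
    region, either as a constant or ``f(cnv_id, sample_id)``. A pair is
    not-assessable when the sample failed yield QC or its regional coverage
    is below ``coverage_min``; otherwise it is concordant when the
    copy-number direction agrees (carrier with a direction-consistent
    match; wild type with no overlapping long-read CNV-type call).
    """
    qc = {s.sample_id: s for s in sample_qc}
    cov = regional_coverage if callable(regional_coverage) else (
        lambda cnv, sample: float(regional_coverage)
    )
    out: list[ConcordanceRecord] = []
    for cnv_id in cn_frame.index:
        iv = cnv_intervals[str(cnv_id)]
        for sample in cn_frame.columns:
            if sample not in qc:
                continue
            cn = float(cn_frame.at[cnv_id, sample])
            state = _short_state(cn)
            recs = records_by_sample.get(sample, ())
            passed = qc[sample].passed
            if not passed or cov(str(cnv_id), sample) < coverage_min:
                out.append(ConcordanceRecord(str(cnv_id), sample, state,
                                             "low_coverage", "not_assessable", passed))
                continue
            overlapping_cnv_type = [
                r for r in recs
                if r.interval.overlap_bp(iv) >= 1
                and r.sv_type in (SVType.DEL, SVType.DUP)
                or (ins_as_dup and r.sv_type is SVType.INS
                    and r.interval.overlap_bp(iv) >= 1)
            ]
            if state == "missing":
                long_state = "none" if not overlapping_cnv_type else (
                    "deletion" if overlapping_cnv_type[0].sv_type is SVType.DEL
                    else "duplication")
                out.append(ConcordanceRecord(str(cnv_id), sample, state, long_state,
                                             "not_assessable", passed))
                continue
            if state == "wildtype":
                classification = "concordant" if not overlapping_cnv_type else "discordant"
                long_state = "none" if not overlapping_cnv_type else (
                    "deletion" if overlapping_cnv_type[0].sv_type is SVType.DEL
                    else "duplication")
            else:
                matches = match_calls(iv, state, recs, mode=mode, ins_as_dup=ins_as_dup)
                classification = "concordant" if matches else "discordant"
                if matches:
                    long_state = state
                elif overlapping_cnv_type:
                    long_state = ("deletion"
                                  if overlapping_cnv_type[0].sv_type is SVType.DEL
                                  else "duplication")
                else:
                    long_state = "none"
            out.append(ConcordanceRecord(str(cnv_id), sample, state, long_state,
                                         classification, passed))
    return out


def summarize_validation(records: Iterable[ConcordanceRecord]) -> pd.DataFrame:
    """Per-CNV concordance table in the style of a validation summary.

    Counts are over samples that passed yield QC and have a defined
    short-read state, split into carrier tallies (N_concordant,
    N_discordant, N_NA over carriers) plus wild-type discordances.
    ``validated_100`` is True iff no carrier is discordant and at least one
    carrier was assessable.
    """
    rows: dict[str, dict[str, float]] = {}
    for r in records:
        if not r.sample_passed or r.short_state == "missing":
            continue
        row = rows.setdefault(r.cnv_id, {
            "n_del_carriers": 0, "n_dup_carriers": 0,
            "n_concordant": 0, "n_discordant": 0, "n_na": 0,
            "n_wildtype": 0, "n_wildtype_discordant": 0,
        })
        if r.short_state == "wildtype":
            row["n_wildtype"] += 1
            if r.classification == "discordant":
                row["n_wildtype_discordant"] += 1
            continue
        if r.short_state == "deletion":
            row["n_del_carriers"] += 1
        else:
            row["n_dup_carriers"] += 1
        if r.classification == "concordant":
            row["n_concordant"] += 1
        elif r.classification == "discordant":
            row["n_discordant"] += 1
        else:
            row["n_na"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    if df.empty:
        return pd.DataFrame(columns=["n_del_carriers", "n_dup_carriers", "n_concordant",
                                     "n_discordant", "n_na", "n_wildtype",
                                     "n_wildtype_discordant", "validated_100"])
    df["validated_100"] = (df["n_discordant"] == 0) & (df["n_concordant"] > 0)
    df.index.name = "cnv_id"
    return df.sort_index()
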