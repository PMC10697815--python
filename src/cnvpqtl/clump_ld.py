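"""Post-association clumping, GWAS overlap, conditional fits and repeats.

Significant CNV units on one chromosome whose copy-number vectors are in
strong LD (squared Spearman rank correlation R^2 > 0.8) are clumped under
the unit with the smallest p-value; units with R^2 < 0.1 to every lead are
independent signals. Units falling in the dead zone 0.1 <= R^2 <= 0.8 to a
lead are not silently absorbed: they seed their own clump, flagged
``correlated_unresolved`` against the nearest such lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import GenomicInterval
from .association import AssociationRecord, fit_association


def spearman_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Spearman rank correlation over pairwise-complete values.

    Ties take average ranks. Returns None (undefined) when fewer than 3
    complete pairs remain or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return None
    xs, ys = x[ok], y[ok]
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        return None
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho * rho)


@dataclass
class ClumpRecord:
    lead_region: str
    protein_id: str
    lead: AssociationRecord
    members: list[AssociationRecord]
    span: GenomicInterval
    correlated_unresolved: bool = False
    nearest_lead: str | None = None


@dataclass(frozen=True)
class GwasHit:
    snp_id: str
    chrom: str
    position: int  # 0-based
    protein_id: str
    p_value: float


def _parse_region_key(region: str) -> GenomicInterval:
    chrom, span = region.split(":")
    start1, end1 = span.split("-")
    return GenomicInterval(chrom, int(start1) - 1, int(end1))


def clump(
    significant: list[AssociationRecord],
    cn_vectors: dict[str, np.ndarray],
    r2_assign: float = 0.8,
    r2_independent: float = 0.1,
) -> list[ClumpRecord]:
    """Greedy clumping of significant units, per protein.

    Repeatedly the unassigned record with the smallest p-value (ties:
    smaller start coordinate) becomes a lead; every unassigned
    same-chromosome, same-protein record with R^2 > ``r2_assign`` to the
    lead joins its clump. Records whose R^2 to some lead lies in
    [``r2_independent``, ``r2_assign``] stay unassigned; when they later
    become leads themselves they carry the ``correlated_unresolved`` flag
    naming the nearest such lead.
    """
    pending = sorted(
        significant,
        key=lambda r: (r.p_value, _parse_region_key(r.region).chrom,
                       _parse_region_key(r.region).start),
    )
    assigned: set[int] = set()
    flagged: dict[int, str] = {}
    clumps: list[ClumpRecord] = []
    intervals = {id(r): _parse_region_key(r.region) for r in pending}

    for lead in pending:
        if id(lead) in assigned:
            continue
        assigned.add(id(lead))
        lead_iv = intervals[id(lead)]
        members = [lead]
        span_start, span_end = lead_iv.start, lead_iv.end
        lead_cn = cn_vectors[lead.region]
        for other in pending:
            if id(other) in assigned or other.protein_id != lead.protein_id:
                continue
            other_iv = intervals[id(other)]
            if other_iv.chrom != lead_iv.chrom:
                continue
            r2 = spearman_r2(lead_cn, cn_vectors[other.region])
            if r2 is None:
                continue
            if r2 > r2_assign:
                assigned.add(id(other))
                members.append(other)
                span_start = min(span_start, other_iv.start)
                span_end = max(span_end, other_iv.end)
            elif r2 >= r2_independent:
                # dead zone: remember the nearest lead it correlates with
                prev = flagged.get(id(other))
                if prev is None:
                    flagged[id(other)] = lead.region
                else:
                    d_new = other_iv.distance_to(lead_iv)
                    d_old = other_iv.distance_to(_parse_region_key(prev))
                    if d_old is None or (d_new is not None and d_new < d_old):
                        flagged[id(other)] = lead.region
        clumps.append(
            ClumpRecord(
                lead_region=lead.region,
                protein_id=lead.protein_id,
                lead=lead,
                members=members,
                span=GenomicInterval(lead_iv.chrom, span_start, span_end),
                correlated_unresolved=id(lead) in flagged,
                nearest_lead=flagged.get(id(lead)),
            )
        )
    return clumps


def overlap_gwas(
    clump_record: ClumpRecord,
    hits: list[GwasHit],
    max_distance: int = 1_000_000,
    p_cutoff: float = 5e-8,
) -> list[GwasHit]:
    """Prior GWAS SNPs for the same protein, genome-wide significant, within 1 Mbp."""
    out = []
    span = clump_record.span
    for h in hits:
        if h.protein_id != clump_record.protein_id or not (h.p_value < p_cutoff):
            continue
        if h.chrom != span.chrom:
            continue
        if span.start <= h.position < span.end:
            dist = 0
        else:
            dist = min(abs(h.position - span.start), abs(h.position - (span.end - 1)))
        if dist < max_distance:
            out.append(h)
    return out


def conditional_fit(
    cn: np.ndarray,
    protein: np.ndarray,
    pcs: np.ndarray | None,
    snp_allele_counts: np.ndarray,
    n_pcs: int = 4,
    threshold: float | None = None,
    region: str = "",
    protein_id: str = "",
) -> tuple[AssociationRecord, bool | None]:
    """Association of CN with protein conditioning on SNP allele counts.

    Returns the CN-coefficient record and, when ``threshold`` is given, a
    flag for whether the conditional p-value stays below it. Raises when CN
    is collinear with the conditioning SNPs (in-sample R^2 = 1).
    """
    cn_arr = np.asarray(cn, dtype=float)
    snps = np.asarray(snp_allele_counts, dtype=float)
    if snps.ndim == 1:
        snps = snps[:, None]
    ok = ~np.isnan(cn_arr) & ~np.isnan(snps).any(axis=1)
    X = np.column_stack([np.ones(int(ok.sum())), snps[ok]])
    y = cn_arr[ok]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = np.sum((y - y.mean()) ** 2)
    if tss > 0 and np.sum(resid**2) / tss < 1e-12:
        raise ValueError("collinear conditioning: CN is determined by the SNP covariates")
    rec = fit_association(
        cn_arr, protein, pcs, n_pcs, region=region, protein_id=protein_id,
        extra_covariates=snps,
    )
    retained = None if threshold is None else bool(rec.p_value < threshold)
    return rec, retained


def annotate_repeats(
    span: GenomicInterval,
    repeats: list[tuple[GenomicInterval, str | None]],
) -> list[tuple[GenomicInterval, str | None, int]]:
    """Repeat intervals overlapping the span by >= 1 bp, with overlap bp."""
    tree = IntervalTree()
    for iv, name in repeats:
        if iv.chrom == span.chrom:
            tree.addi(iv.start, iv.end, (iv, name))
    out = []
    for hit in sorted(tree.overlap(span.start, span.end)):
        iv, name = hit.data
        out.append((iv, name, iv.overlap_bp(span)))
    return out
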