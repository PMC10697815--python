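"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* In memory everything is 0-based, half-open; the caller-TSV dialect and VCF
  are 1-based inclusive at the file boundary only.
* Chromosome names are stored without a ``chr`` prefix; readers strip it.

Caller TSV dialect
------------------
Whitespace-separated, no header, one call per line::

    [sample_id]  sv_type  chrom:start-end  size  cn  p_value  q0

with ``start-end`` 1-based inclusive. The leading ``sample_id`` column is
optional: native per-sample caller output omits it (pass ``sample_id=`` to
the reader), cohort files written by :func:`write_calls` include it.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import CohortTables, Genotype, GenomicInterval, RawCall, SVRecord, SVType

_COORD_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class ParseError(ValueError):
    """Malformed record in an input file; message names the offending line."""


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (1-based inclusive) into an internal interval."""
    m = _COORD_RE.match(text.strip())
    if m is None:
        raise ParseError(f"malformed coordinate string {text!r}")
    start1 = int(m.group("start"))
    end1 = int(m.group("end"))
    if start1 < 1 or end1 < start1:
        raise ParseError(f"invalid 1-based span {text!r}")
    return GenomicInterval(m.group("chrom"), start1 - 1, end1)


def format_region(iv: GenomicInterval) -> str:
    """Render an interval in the 1-based inclusive ``chrom:start-end`` dialect."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


# ---------------------------------------------------------------------------
# CNV call tables
# ---------------------------------------------------------------------------

def read_calls(
    path: str | Path,
    dialect: str = "cnvnator_tsv",
    sample_id: str | None = None,
) -> list[RawCall]:
    """Read per-sample CNV calls from the caller TSV dialect.

    Lines with 6 fields take their sample id from ``sample_id`` (default:
    the file stem); lines with 7 fields carry it in the first column. The
    ``size`` column is cross-checked against the interval width; on mismatch
    a warning is emitted and the interval wins.
    """
    if dialect != "cnvnator_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    default_sample = sample_id if sample_id is not None else path.stem
    calls: list[RawCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 7:
                sid, sv_type, coord, size, cn, p, q0 = fields
            elif len(fields) == 6:
                sid = default_sample
                sv_type, coord, size, cn, p, q0 = fields
            else:
                raise ParseError(f"{path}:{lineno}: expected 6 or 7 fields, got {len(fields)}")
            try:
                iv = parse_region(coord)
                call = RawCall(
                    sample_id=sid,
                    sv_type=sv_type,
                    interval=iv,
                    cn=float(cn),
                    p_value=float(p),
                    q0=float(q0),
                )
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if int(size) != iv.width:
                warnings.warn(
                    f"{path}:{lineno}: size column {size} != interval width {iv.width}; "
                    "using the interval",
                    stacklevel=2,
                )
            calls.append(call)
    return calls


def write_calls(calls: Iterable[RawCall], path: str | Path) -> None:
    """Write calls in the 7-column cohort dialect (with sample_id)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.sv_type}\t{format_region(c.interval)}\t"
                f"{c.interval.width}\t{c.cn:.6g}\t{c.p_value:.6g}\t{c.q0:.6g}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_MAP = {
    (0, 0): Genotype.HOM_REF,
    (0, 1): Genotype.HET,
    (1, 0): Genotype.HET,
    (1, 1): Genotype.HOM_ALT,
}


def _classify_gt(gt: tuple | None) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    key = tuple(min(int(a), 1) for a in gt)
    return _GT_MAP.get(key, Genotype.HOM_ALT)


def read_sv_vcf(path: str | Path, caller: str | None = None) -> list[SVRecord]:
    """Read structural variants from a VCF with SVTYPE/END/SVLEN annotations.

    DEL/DUP/INV span POS..END (END recovered from SVLEN when absent); INS are
    anchored as width-1 intervals at POS. Records with neither END nor SVLEN
    are skipped with a warning. One :class:`SVRecord` is emitted per sample
    in the VCF per record.
    """
    records: list[SVRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        caller_name = caller or Path(path).stem
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                n_skipped += 1
                continue
            try:
                svtype = SVType(str(svtype))
            except ValueError:
                n_skipped += 1
                continue
            start = rec.start  # 0-based
            if svtype is SVType.INS or svtype is SVType.BND:
                end = start + 1
            else:
                end = rec.stop
                try:
                    svlen = rec.info.get("SVLEN")
                except (KeyError, ValueError):  # SVLEN not declared in header
                    svlen = None
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0] if svlen else None
                if svlen is not None and end - start == abs(int(svlen)) + 1:
                    # span was derived from SVLEN (no explicit END): htslib
                    # applies the padding-base convention; the caller dialect
                    # counts width = |SVLEN| from POS
                    end = start + abs(int(svlen))
                elif end - start <= 1:
                    if svlen is not None and abs(int(svlen)) >= 1:
                        end = start + abs(int(svlen))
                    else:  # neither a usable END nor SVLEN
                        n_skipped += 1
                        continue
            if end <= start:
                n_skipped += 1
                continue
            iv = GenomicInterval(rec.chrom, start, end)
            if rec.samples:
                for sample in rec.samples:
                    gt = rec.samples[sample].get("GT")
                    records.append(SVRecord(sample, svtype, iv, _classify_gt(gt), caller_name))
            else:
                records.append(SVRecord(caller_name, svtype, iv, Genotype.MISSING, caller_name))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} SV records without usable span", stacklevel=2)
    return records


_GT_TEXT = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_sv_vcf(
    records: Sequence[SVRecord],
    path: str | Path,
    chromosome_lengths: Mapping[str, int],
    sample_id: str | None = None,
) -> None:
    """Write a single-sample SV VCF (SVTYPE/END/SVLEN in INFO, GT in FORMAT)."""
    if sample_id is None:
        samples = sorted({r.sample_id for r in records})
        if len(samples) > 1:
            raise ValueError("records span multiple samples; pass sample_id or split first")
        sample_id = samples[0] if samples else "sample"
    header = pysam.VariantHeader()
    for chrom, length in chromosome_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)
    alt_of = {SVType.DEL: "<DEL>", SVType.DUP: "<DUP>", SVType.INS: "<INS>",
              SVType.INV: "<INV>", SVType.BND: "<BND>"}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.interval.chrom, r.interval.start)):
            if r.sv_type in (SVType.INS, SVType.BND):
                stop = r.interval.start + 1
            else:
                stop = r.interval.end
            rec = out.new_record(
                contig=r.interval.chrom,
                start=r.interval.start,
                stop=stop,
                alleles=("N", alt_of[r.sv_type]),
            )
            rec.info["SVTYPE"] = r.sv_type.value
            gt_text = _GT_TEXT[r.genotype]
            rec.samples[sample_id]["GT"] = (
                tuple(None if a == "." else int(a) for a in gt_text.split("/"))
            )
            out.write(rec)


def read_snp_vcf(path: str | Path) -> pd.DataFrame:
    """Read a SNP VCF into a samples x variants allele-count matrix (0/1/2, NaN)."""
    counts: dict[str, list[float]] = {}
    ids: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for sample in samples:
            counts[sample] = []
        for rec in vcf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            ids.append(vid)
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    counts[sample].append(np.nan)
                else:
                    counts[sample].append(float(sum(min(int(a), 1) for a in gt)))
    return pd.DataFrame(counts, index=ids).T


def write_snp_vcf(
    genotypes: pd.DataFrame,
    positions: Mapping[str, tuple[str, int]],
    path: str | Path,
    chromosome_lengths: Mapping[str, int],
) -> None:
    """Write a samples x variants allele-count matrix as a biallelic SNP VCF.

    ``positions`` maps variant id -> (chrom, 0-based position).
    """
    header = pysam.VariantHeader()
    for chrom, length in chromosome_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in genotypes.index:
        header.add_sample(str(s))
    order = sorted(genotypes.columns, key=lambda v: positions[v])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for vid in order:
            chrom, pos0 = positions[vid]
            rec = out.new_record(contig=chrom, start=pos0, alleles=("A", "G"), id=vid)
            for s in genotypes.index:
                ac = genotypes.at[s, vid]
                if np.isnan(ac):
                    rec.samples[str(s)]["GT"] = (None, None)
                else:
                    ac = int(ac)
                    rec.samples[str(s)]["GT"] = (1 if ac >= 1 else 0, 1 if ac >= 2 else 0)
            out.write(rec)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED3 (BED4 when *names* given), sorted (chrom, start, end)."""
    ivs = list(intervals)
    if names is not None:
        if len(names) != len(ivs):
            raise ValueError("names length differs from intervals")
        rows = sorted(zip(ivs, names), key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    else:
        rows = [(iv, None) for iv in sorted(ivs, key=lambda i: (i.chrom, i.start, i.end))]
    with open(path, "w") as fh:
        for iv, name in rows:
            if name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str | None]]:
    """Read BED3/BED4/BED6; returns (interval, name-or-None) pairs."""
    out: list[tuple[GenomicInterval, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line with < 3 columns")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            name = fields[3] if len(fields) > 3 else None
            out.append((iv, name))
    return out


# ---------------------------------------------------------------------------
# Tabular (TSV) matrices
# ---------------------------------------------------------------------------

def write_cn_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a CN matrix with ``chrom:start-end`` (1-based) row labels, NA for missing."""
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="region")


def read_cn_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="region", na_values="NA")


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def read_table(path: str | Path, index_col: str = "sample_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values="NA")


def read_chromosome_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV ``chrom<TAB>length`` -> ordered dict of lengths."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom.removeprefix("chr")] = int(length)
    return out


def read_cohort_tables(
    proteins: str | Path,
    covariates: str | Path,
    pcs: str | Path,
    snp_vcf: str | Path | None = None,
) -> CohortTables:
    prot = read_table(proteins)
    cov = read_table(covariates)
    pc = read_table(pcs)
    snps = read_snp_vcf(snp_vcf) if snp_vcf is not None else None
    common = prot.index
    return CohortTables(
        proteins=prot,
        covariates=cov.loc[common],
        pcs=pc.loc[common],
        snp_genotypes=snps.loc[common] if snps is not None else None,
    )
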