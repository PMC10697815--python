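"""Core domain types shared across the pipeline.

All genomic coordinates are held 0-based, half-open in memory. The 1-based
inclusive convention used by the CNV-caller TSV dialect and by VCF exists
only at the file boundary (see :mod:`cnvpqtl.io_formats`). Chromosome names
are stored without a ``chr`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class SVType(str, Enum):
    """Structural-variant classes as reported by long-read SV callers."""

    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    BND = "BND"


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; chromosome names are bare in memory."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if not c:
        raise ValueError("empty chromosome name")
    return c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name without ``chr`` prefix.
    start, end : int
        0-based half-open bounds; ``end > start`` except for width-1
        insertion anchors created with ``end = start + 1``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError("negative start coordinate")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Minimal bp gap to *other*; 0 when overlapping/abutting, None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlap_bp(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def __str__(self) -> str:  # 1-based inclusive display, matching the TSV dialect
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class RawCall:
    """One per-sample read-depth CNV detection.

    ``cn`` is the real-valued copy-number estimate (2 = diploid wild-type);
    ``p_value`` the one-sample t-test significance of the regional depth
    against the global depth; ``q0`` the fraction of low-quality/ambiguously
    aligned reads within the call region.
    """

    sample_id: str
    sv_type: str  # "deletion" | "duplication"
    interval: GenomicInterval
    cn: float
    p_value: float
    q0: float

    def __post_init__(self) -> None:
        if self.sv_type not in ("deletion", "duplication"):
            raise ValueError(f"unknown CNV type {self.sv_type!r}")
        if self.cn < 0:
            raise ValueError("negative copy number")
        if self.sv_type == "deletion" and not self.cn < 2:
            raise ValueError(f"deletion with CN {self.cn} >= 2")
        if self.sv_type == "duplication" and not self.cn > 2:
            raise ValueError(f"duplication with CN {self.cn} <= 2")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        if not (0 <= self.q0 <= 1):
            raise ValueError(f"q0 {self.q0} outside [0, 1]")


@dataclass(frozen=True)
class SVRecord:
    """A long-read structural-variant call for one sample."""

    sample_id: str
    sv_type: SVType
    interval: GenomicInterval
    genotype: Genotype
    caller: str = "unknown"


@dataclass
class CohortTables:
    """Sample-aligned cohort measurements.

    ``proteins``: samples x proteins DataFrame (NaN = missing);
    ``covariates``: per-sample age / sex / batch; ``pcs``: samples x k
    genetic principal components; ``snp_genotypes``: samples x variants
    allele counts (0/1/2, NaN = missing). All tables share the sample index.
    """

    proteins: "pandas.DataFrame"  # noqa: F821 - typing only
    covariates: "pandas.DataFrame"  # noqa: F821
    pcs: "pandas.DataFrame"  # noqa: F821
    snp_genotypes: "pandas.DataFrame | None" = None  # noqa: F821

    def __post_init__(self) -> None:
        idx = self.proteins.index
        for name, tab in (("covariates", self.covariates), ("pcs", self.pcs)):
            if not idx.equals(tab.index):
                raise ValueError(f"{name} index differs from protein index")
        if self.snp_genotypes is not None and not idx.equals(self.snp_genotypes.index):
            raise ValueError("snp_genotypes index differs from protein index")
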