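"""Core domain objects shared across the pipeline.

Coordinate conventions: variant positions are 1-based (VCF style);
all intervals (genes, exons, zones, bins, TADs) are 0-based half-open
(BED style). Conversions happen only in :mod:`lethalmap.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "MappingZone",
    "GeneModel",
    "GenomeModel",
    "VariantCall",
    "MarkerDef",
    "StrainRecord",
    "FilterParams",
    "variant_ratio",
    "expected_ratio",
    "UndefinedRatioError",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


class UndefinedRatioError(ValueError):
    """Raised when an allelic ratio is requested for a site with no reads."""


@dataclass(frozen=True)
class MappingZone:
    """A genetic-mapping interval inside the balanced region.

    Classical complementation/mapping assigns each lethal mutation to a
    zone; candidate variants outside a strain's mapped zone are suspect.
    """

    zone_id: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ConfigurationError(f"bad zone interval {self.start}..{self.end}")

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with exon structure and planted ground truth.

    ``exons`` are genomic 0-based half-open intervals, sorted by start and
    disjoint, all within ``[start, end)``. ``group`` labels the essentiality
    class used in downstream comparisons (G1: screen-derived essential,
    G2: balanced-region essential, G3: other essential, G4: non-essential).
    """

    gene_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    essential: bool = False
    group: str = "none"
    zone_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ConfigurationError(f"{self.gene_id}: strand must be + or -")
        prev_end = self.start - 1
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise ConfigurationError(f"{self.gene_id}: exon [{s},{e}) outside gene body")
            if s <= prev_end:
                raise ConfigurationError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e - 1

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class GenomeModel:
    """A single synthetic chromosome with genes, mapping zones and the
    interval covered by the rescuing duplication (the balanced region)."""

    chrom_name: str
    chrom_length: int
    genes: list[GeneModel]
    zones: list[MappingZone]
    balanced_region: tuple[int, int]
    seq: Optional[str] = None  # reference sequence, needed for consequence calls

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.start < 0 or g.end > self.chrom_length:
                raise ConfigurationError(f"{g.gene_id} outside chromosome bounds")
        if self.seq is not None and len(self.seq) != self.chrom_length:
            raise ConfigurationError("sequence length != chrom_length")

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_overlapping(self, start: int, end: int) -> list[GeneModel]:
        return [g for g in self.genes if g.overlaps(start, end)]

    def gene_at(self, pos0: int) -> Optional[GeneModel]:
        for g in self.genes:
            if g.contains(pos0):
                return g
        return None

    def zone_at(self, pos0: int) -> Optional[MappingZone]:
        for z in self.zones:
            if z.contains(pos0):
                return z
        return None


@dataclass(frozen=True)
class VariantCall:
    """One SNV with strand-split allele read counts.

    ``pos`` is 1-based. The allelic ratio (allele balance) of the site is
    alt/(alt+ref); balanced heterozygous lethals in a 2:1 copy system sit
    near 2/3, duplication-uncovered homozygous sites near 1.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int

    def __post_init__(self) -> None:
        if min(self.alt_fwd, self.alt_rev, self.ref_fwd, self.ref_rev) < 0:
            raise ValueError("negative read count")
        if self.total_reads < 1:
            raise ValueError("variant with zero total reads")
        if self.ref == self.alt:
            raise ValueError("ref == alt")

    @property
    def alt_reads(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def ref_reads(self) -> int:
        return self.ref_fwd + self.ref_rev

    @property
    def total_reads(self) -> int:
        return self.alt_fwd + self.alt_rev + self.ref_fwd + self.ref_rev

    @property
    def key(self) -> tuple[str, int, str]:
        """Allele identity used for background subtraction: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt)


def variant_ratio(v: VariantCall) -> float:
    """Fraction of reads supporting the alternate allele.

    Raises :class:`UndefinedRatioError` on zero total depth (cannot occur
    for a validated :class:`VariantCall` but guards raw tuples).
    """
    total = v.total_reads
    if total < 1:
        raise UndefinedRatioError(f"no reads at {v.chrom}:{v.pos}")
    return v.alt_reads / total


def expected_ratio(mutant_copies: int, total_copies: int) -> float:
    """Expected allele balance from the copy-number configuration.

    A lethal allele balanced by a free duplication carrying the wild-type
    copy is present on 2 of 3 copies -> 2/3; a site the duplication does
    not cover is homozygous on 2 of 2 copies -> 1.0.
    """
    if total_copies <= 0:
        raise ValueError("total_copies must be positive")
    if not 0 < mutant_copies <= total_copies:
        raise ValueError("need 0 < mutant_copies <= total_copies")
    return mutant_copies / total_copies


@dataclass(frozen=True)
class MarkerDef:
    """A visible-marker mutation used as a strain identity check."""

    name: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    expected_ratio: float
    balanced: bool  # True if covered (rescued) by the duplication

    def __post_init__(self) -> None:
        if not 0 < self.expected_ratio <= 1:
            raise ConfigurationError(f"{self.name}: expected_ratio out of (0,1]")


@dataclass
class StrainRecord:
    """A mutant strain's called variants plus QC state.

    ``marker_status`` maps marker name -> observed ratio, or None when the
    marker variant is absent. ``qc_verdict`` is None until QC runs.
    """

    strain_id: str
    variants: list[VariantCall]
    mean_depth: float
    marker_status: dict[str, Optional[float]] = field(default_factory=dict)
    qc_verdict: Optional[str] = None  # pass | fail_marker | fail_coverage

    def with_verdict(self, verdict: str, marker_status: dict[str, Optional[float]]) -> "StrainRecord":
        return replace(self, qc_verdict=verdict, marker_status=dict(marker_status))


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the lethal-candidate variant filter.

    Defaults: allele-balance band 0.40-0.90 inclusive, >=8 alt reads with
    at least one on each strand, and >=8X genome-wide mean depth per strain
    (a strain strictly below 8X is discarded).
    """

    ratio_low: float = 0.40
    ratio_high: float = 0.90
    min_alt_reads: int = 8
    require_both_strands: bool = True
    min_mean_depth: float = 8.0

    def __post_init__(self) -> None:
        if not 0 <= self.ratio_low < self.ratio_high <= 1:
            raise ConfigurationError("need 0 <= ratio_low < ratio_high <= 1")
        if self.min_alt_reads < 0 or self.min_mean_depth < 0:
            raise ConfigurationError("negative threshold")
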