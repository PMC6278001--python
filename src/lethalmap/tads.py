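"""TAD-boundary gene classification and enrichment testing.

Boundaries are the genomic regions between consecutive domains,
optionally widened by a flank; genes are classified by any-overlap of
the gene body (or, optionally, by their transcription start site).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .models import ConfigurationError, GeneModel
from .simulate import TADSet
from .stats import fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = ["TADSet", "BoundaryEnrichment", "derive_boundaries", "classify_gene", "boundary_enrichment"]


def derive_boundaries(tadset: TADSet, flank: int = 0) -> list[tuple[int, int]]:
    """Inter-TAD regions, widened by ``flank`` bp on each side.

    For consecutive TADs [a,b) and [c,d), the boundary is
    [b - flank, c + flank) clipped to the chromosome; touching TADs
    (b == c) with flank 0 would give an empty region, so a zero-width
    gap only yields a boundary when flank > 0.
    """
    bounds = []
    for (_, b), (c, _) in zip(tadset.tads, tadset.tads[1:]):
        s = max(0, b - flank)
        e = min(tadset.chrom_length, c + flank)
        if s < e:
            bounds.append((s, e))
    return bounds


def classify_gene(
    gene: GeneModel,
    tadset: TADSet,
    flank: int = 0,
    mode: str = "body",
) -> str:
    """Classify a gene as ``boundary``, ``interior`` or ``outside``.

    ``mode='body'`` uses any-overlap of the full gene interval;
    ``mode='tss'`` uses the transcription start (5' end, strand-aware)
    as a point. Boundary takes precedence over interior.
    """
    if mode == "tss":
        p = gene.start if gene.strand == "+" else gene.end - 1
        span = (p, p + 1)
    elif mode == "body":
        span = (gene.start, gene.end)
    else:
        raise ConfigurationError(f"unknown overlap mode {mode!r}")
    s, e = span
    for bs, be in derive_boundaries(tadset, flank):
        if bs < e and s < be:
            return "boundary"
    for ts, te in tadset.tads:
        if ts < e and s < te:
            return "interior"
    return "outside"


@dataclass(frozen=True)
class BoundaryEnrichment:
    label_a: str
    label_b: str
    # rows: group A / group B; cols: boundary / interior
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    n_outside: int


def boundary_enrichment(
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    tadset: TADSet,
    flank: int = 0,
    mode: str = "body",
    label_a: str = "A",
    label_b: str = "B",
) -> BoundaryEnrichment:
    """Two-sided Fisher's exact test of boundary occupancy between two
    gene groups. Genes outside all TADs and boundaries are excluded from
    the table (their count is reported)."""
    if not genes_a or not genes_b:
        raise ConfigurationError("empty gene group")
    counts = {}
    n_outside = 0
    for label, genes in ((label_a, genes_a), (label_b, genes_b)):
        bnd = inte = 0
        for g in genes:
            cls = classify_gene(g, tadset, flank=flank, mode=mode)
            if cls == "boundary":
                bnd += 1
            elif cls == "interior":
                inte += 1
            else:
                n_outside += 1
        counts[label] = (bnd, inte)
    if n_outside:
        logger.info("%d genes outside all TADs excluded from the 2x2 table", n_outside)
    table = (counts[label_a], counts[label_b])
    odds, p = fisher_exact_2x2(table)
    return BoundaryEnrichment(
        label_a=label_a, label_b=label_b, table=table,
        odds_ratio=odds, p_value=p, n_outside=n_outside,
    )
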