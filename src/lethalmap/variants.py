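"""Strain-level QC and balanced-lethal SNV filtering.

The screen rests on allele balance: a recessive lethal rescued by a free
duplication is carried on two of three copies of the locus, so reads
supporting the mutant allele should make up roughly two thirds of the
pileup. Candidate lethals are SNVs whose allele balance falls in a band
around that expectation, with solid read support on both strands, after
subtracting variants already present in the un-mutagenized starting
strain.

Filters are pure functions over lists of :class:`~lethalmap.models.VariantCall`;
each is idempotent and they commute, so the pipeline order is a matter of
reporting, not of result.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .models import (
    FilterParams,
    MarkerDef,
    StrainRecord,
    VariantCall,
    variant_ratio,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AmbiguousLocusError",
    "check_markers",
    "qc_strains",
    "filter_ratio_band",
    "filter_read_support",
    "subtract_background",
    "apply_filters",
    "FilterAudit",
]


class AmbiguousLocusError(ValueError):
    """Two variant records at the same marker locus in one strain."""


def check_markers(
    strain: StrainRecord,
    markers: Sequence[MarkerDef],
    params: FilterParams,
) -> dict[str, Optional[float]]:
    """Locate each marker mutation in a strain and report its allele balance.

    A marker is *found* when a variant with the marker's alternate allele
    exists at its locus and its ratio lies in the marker's acceptance
    window: the candidate band ``[ratio_low, ratio_high]`` for a
    duplication-balanced marker, ``>= ratio_high`` for an unbalanced one.
    Absent or out-of-window markers map to None.
    """
    status: dict[str, Optional[float]] = {}
    for m in markers:
        hits = [
            v
            for v in strain.variants
            if v.chrom == m.chrom and v.pos == m.pos and v.alt == m.alt
        ]
        if len(hits) > 1:
            raise AmbiguousLocusError(
                f"{strain.strain_id}: {len(hits)} variant records at marker "
                f"locus {m.chrom}:{m.pos}"
            )
        if not hits:
            status[m.name] = None
            continue
        r = variant_ratio(hits[0])
        if m.balanced:
            ok = params.ratio_low <= r <= params.ratio_high
        else:
            ok = r >= params.ratio_high
        status[m.name] = r if ok else None
    return status


@dataclass(frozen=True)
class Rejection:
    strain_id: str
    reason: str  # fail_marker | fail_coverage
    detail: str


def qc_strains(
    cohort: Iterable[StrainRecord],
    markers: Sequence[MarkerDef],
    params: FilterParams,
) -> tuple[list[StrainRecord], list[Rejection]]:
    """Strain-level QC: marker identity check first, then coverage.

    Returns the passing strains (input order preserved, each stamped with
    ``qc_verdict`` and marker status) and a report listing every rejection
    with its reason. A strain missing any marker fails as ``fail_marker``
    even if it is also under-sequenced; coverage strictly below
    ``min_mean_depth`` fails as ``fail_coverage`` (exactly the threshold
    passes).
    """
    passing: list[StrainRecord] = []
    rejections: list[Rejection] = []
    for s in cohort:
        status = check_markers(s, markers, params)
        missing = [name for name, r in status.items() if r is None]
        if missing:
            rejections.append(
                Rejection(s.strain_id, "fail_marker", "missing: " + ",".join(missing))
            )
            continue
        if s.mean_depth < params.min_mean_depth:
            rejections.append(
                Rejection(
                    s.strain_id,
                    "fail_coverage",
                    f"mean depth {s.mean_depth:.1f}X < {params.min_mean_depth:g}X",
                )
            )
            continue
        passing.append(s.with_verdict("pass", status))
    return passing, rejections


def filter_ratio_band(
    variants: Iterable[VariantCall], params: FilterParams
) -> list[VariantCall]:
    """Keep SNVs whose allele balance lies in [ratio_low, ratio_high], inclusive."""
    return [
        v for v in variants if params.ratio_low <= variant_ratio(v) <= params.ratio_high
    ]


def filter_read_support(
    variants: Iterable[VariantCall], params: FilterParams
) -> list[VariantCall]:
    """Keep SNVs with >= min_alt_reads alternate reads, and (by default)
    at least one alternate read on each strand."""
    kept = []
    for v in variants:
        if v.alt_reads < params.min_alt_reads:
            continue
        if params.require_both_strands and (v.alt_fwd < 1 or v.alt_rev < 1):
            continue
        kept.append(v)
    return kept


def subtract_background(
    variants: Iterable[VariantCall],
    background: set[tuple[str, int, str]],
) -> list[VariantCall]:
    """Remove variants present in the starting-strain background set.

    Matching is allele-aware on (chrom, pos, alt): a different alternate
    allele at a background position is retained. Background entries are
    (chrom, 1-based pos, alt) tuples.
    """
    background_pos = {(c, p) for c, p, _ in background}
    kept = []
    for v in variants:
        if v.key in background:
            continue
        if (v.chrom, v.pos) in background_pos:
            logger.warning(
                "variant %s:%d %s>%s shares a background position but not the "
                "background allele; retained",
                v.chrom,
                v.pos,
                v.ref,
                v.alt,
            )
        kept.append(v)
    return kept


@dataclass(frozen=True)
class FilterAudit:
    """Per-variant verdict of each filter, for the audit trail."""

    variant: VariantCall
    ratio: float
    in_band: bool
    read_support: bool
    not_background: bool

    @property
    def survives(self) -> bool:
        return self.in_band and self.read_support and self.not_background


def apply_filters(
    strain: StrainRecord,
    background: set[tuple[str, int, str]],
    params: FilterParams,
    markers: Sequence[MarkerDef] = (),
) -> tuple[list[VariantCall], list[FilterAudit]]:
    """Run the full candidate filter on one strain and keep an audit trail.

    Marker loci are excluded from candidacy (they are engineered, known
    mutations, not lethal candidates).
    """
    marker_keys = {(m.chrom, m.pos, m.alt) for m in markers}
    audits: list[FilterAudit] = []
    for v in strain.variants:
        if v.key in marker_keys:
            continue
        r = variant_ratio(v)
        audits.append(
            FilterAudit(
                variant=v,
                ratio=r,
                in_band=params.ratio_low <= r <= params.ratio_high,
                read_support=bool(
                    v.alt_reads >= params.min_alt_reads
                    and (not params.require_both_strands or (v.alt_fwd >= 1 and v.alt_rev >= 1))
                ),
                not_background=v.key not in background,
            )
        )
    surviving = [a.variant for a in audits if a.survives]
    return surviving, audits
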