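"""Readers and writers for the pipeline's on-disk formats.

All coordinate conversion lives here: VCF records are 1-based, BED
intervals 0-based half-open. Strand-split allele depths travel in four
integer INFO fields (SRF/SRR reference forward/reverse, SAF/SAR
alternate forward/reverse). Strain-level metadata (id, mean depth) ride
as extra ``##`` header lines. Writers emit deterministic, diff-friendly
text; every writer has a reader that round-trips exactly.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .models import (
    GeneModel,
    GenomeModel,
    MappingZone,
    MarkerDef,
    StrainRecord,
    VariantCall,
)

__all__ = [
    "write_strain_vcf",
    "read_strain_vcf",
    "write_genes",
    "read_genes",
    "write_zones",
    "read_zones",
    "write_markers",
    "read_markers",
    "write_background",
    "read_background",
    "write_contact_matrix",
    "read_contact_matrix",
    "write_tads",
    "read_tads",
    "write_ppi",
    "read_ppi",
    "write_expression",
    "read_expression",
]


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=lethalmap
##contig=<ID={chrom},length={length}>
##strain_id={strain_id}
##mean_depth={mean_depth!r}
##INFO=<ID=SRF,Number=1,Type=Integer,Description="Reference reads, forward strand">
##INFO=<ID=SRR,Number=1,Type=Integer,Description="Reference reads, reverse strand">
##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alternate reads, forward strand">
##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alternate reads, reverse strand">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_strain_vcf(strain: StrainRecord, path, chrom: str, chrom_length: int) -> None:
    with open(path, "w") as fh:
        fh.write(
            _VCF_HEADER.format(
                chrom=chrom,
                length=chrom_length,
                strain_id=strain.strain_id,
                mean_depth=strain.mean_depth,
            )
        )
        for v in strain.variants:
            info = f"SRF={v.ref_fwd};SRR={v.ref_rev};SAF={v.alt_fwd};SAR={v.alt_rev}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")


def read_strain_vcf(path) -> StrainRecord:
    """Parse one per-strain VCF back into a StrainRecord.

    Indels (multi-base alleles) are skipped: only SNVs enter the
    pipeline.
    """
    strain_id, mean_depth = Path(str(path)).stem, float("nan")
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##strain_id="):
                strain_id = line.split("=", 1)[1].strip()
            elif line.startswith("##mean_depth="):
                mean_depth = float(line.split("=", 1)[1])
    variants = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else None
            if alt is None or len(rec.ref) != 1 or len(alt) != 1:
                continue  # not an SNV
            variants.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    alt_fwd=int(rec.info["SAF"]),
                    alt_rev=int(rec.info["SAR"]),
                    ref_fwd=int(rec.info["SRF"]),
                    ref_rev=int(rec.info["SRR"]),
                )
            )
    return StrainRecord(strain_id=strain_id, variants=variants, mean_depth=mean_depth)


# ---------------------------------------------------------------------------
# genes / zones / markers / background

_GENE_COLUMNS = [
    "chrom", "start", "end", "gene_id", "strand", "exon_starts", "exon_ends",
    "essential", "group", "zone_id",
]


def write_genes(genome: GenomeModel, path) -> None:
    """Gene models as a BED-like TSV (0-based half-open, exon block lists)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_GENE_COLUMNS)
        for g in genome.genes:
            w.writerow(
                [
                    genome.chrom_name, g.start, g.end, g.gene_id, g.strand,
                    ",".join(str(a) for a, _ in g.exons),
                    ",".join(str(b) for _, b in g.exons),
                    int(g.essential), g.group, g.zone_id or ".",
                ]
            )


def read_genes(path) -> list[GeneModel]:
    genes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            starts = [int(x) for x in row["exon_starts"].split(",") if x]
            ends = [int(x) for x in row["exon_ends"].split(",") if x]
            genes.append(
                GeneModel(
                    gene_id=row["gene_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    exons=tuple(zip(starts, ends)),
                    essential=bool(int(row["essential"])),
                    group=row["group"],
                    zone_id=None if row["zone_id"] == "." else row["zone_id"],
                )
            )
    return genes


def write_zones(zones: Sequence[MappingZone], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["zone_id", "start", "end"])
        for z in zones:
            w.writerow([z.zone_id, z.start, z.end])


def read_zones(path) -> list[MappingZone]:
    with open(path, newline="") as fh:
        return [
            MappingZone(r["zone_id"], int(r["start"]), int(r["end"]))
            for r in csv.DictReader(fh, delimiter="\t")
        ]


def write_markers(markers: Sequence[MarkerDef], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "chrom", "pos", "ref", "alt", "expected_ratio", "balanced"])
        for m in markers:
            w.writerow([m.name, m.chrom, m.pos, m.ref, m.alt, repr(m.expected_ratio), int(m.balanced)])


def read_markers(path) -> list[MarkerDef]:
    with open(path, newline="") as fh:
        return [
            MarkerDef(
                r["name"], r["chrom"], int(r["pos"]), r["ref"], r["alt"],
                float(r["expected_ratio"]), bool(int(r["balanced"])),
            )
            for r in csv.DictReader(fh, delimiter="\t")
        ]


def write_background(background: Iterable[tuple[str, int, str]], path) -> None:
    """Starting-strain variant loci as (chrom, 1-based pos, alt)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "alt"])
        for chrom, pos, alt in sorted(background):
            w.writerow([chrom, pos, alt])


def read_background(path) -> set[tuple[str, int, str]]:
    with open(path, newline="") as fh:
        return {
            (r["chrom"], int(r["pos"]), r["alt"])
            for r in csv.DictReader(fh, delimiter="\t")
        }


# ---------------------------------------------------------------------------
# Hi-C / TADs


def write_contact_matrix(m, pairs_path, bins_path) -> None:
    """Bin-pair TSV (upper triangle incl. diagonal, non-zero only) + bin BED."""
    import numpy as np

    with open(bins_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for k, (s, e) in enumerate(m.bins):
            w.writerow([m.chrom, s, e, f"bin_{k}"])
    ii, jj = np.triu_indices(m.n_bins)
    with open(pairs_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["bin_i", "bin_j", "count"])
        for i, j in zip(ii, jj):
            c = int(m.counts[i, j])
            if c:
                w.writerow([int(i), int(j), c])


def read_contact_matrix(pairs_path, bins_path):
    import numpy as np

    from .hic import ContactMatrix

    bins, chrom = [], None
    with open(bins_path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            chrom = row[0]
            bins.append((int(row[1]), int(row[2])))
    n = len(bins)
    counts = np.zeros((n, n), dtype=np.int64)
    with open(pairs_path, newline="") as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            i, j, c = int(r["bin_i"]), int(r["bin_j"]), int(r["count"])
            counts[i, j] = c
            counts[j, i] = c
    widths = {e - s for s, e in bins[:-1]}
    partial = len(bins) > 1 and (bins[-1][1] - bins[-1][0]) not in widths
    return ContactMatrix(chrom=chrom, bins=bins, counts=counts, partial_last_bin=partial)


def write_tads(tadset, path, chrom: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s, e in tadset.tads:
            w.writerow([chrom, s, e])


def read_tads(path, chrom_length: int):
    from .simulate import TADSet

    tads = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            tads.append((int(row[1]), int(row[2])))
    return TADSet(tads=tads, chrom_length=chrom_length)


# ---------------------------------------------------------------------------
# PPI / expression


def write_ppi(edges: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_a", "gene_b"])
        for u, v in edges:
            w.writerow([u, v])


def read_ppi(path) -> list[tuple[str, str]]:
    with open(path, newline="") as fh:
        return [(r["gene_a"], r["gene_b"]) for r in csv.DictReader(fh, delimiter="\t")]


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
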