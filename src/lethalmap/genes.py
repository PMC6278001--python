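"""Mapping surviving SNVs to genes, consequence annotation, mapping-zone
screening, evidence integration, and allele-to-gene grouping.

The final call of an essential gene rests on three lines of evidence:
the candidate variant lies in the genetic-mapping zone assigned to the
strain's lethal; the gene has independent lethality support (RNAi
phenotype or a known lethal allele); and no homozygous-viable disruptive
allele of the gene exists in a large mutant catalog (a gene tolerating a
nonsense or splice allele in viable homozygotes is unlikely to be
essential). The tier rule formalizing this is documented on
:func:`integrate_evidence`.
"""
from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

from .models import ConfigurationError, GeneModel, GenomeModel, VariantCall

__all__ = [
    "ConsequenceCall",
    "EvidenceRecord",
    "Candidate",
    "EssentialGeneCall",
    "Table1Record",
    "Table1Summary",
    "annotate_consequence",
    "map_to_genes",
    "screen_by_zone",
    "integrate_evidence",
    "group_alleles",
    "parse_table1",
    "write_table1",
    "summarize_table1",
    "packaged_table1_path",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class ConsequenceCall:
    """Predicted molecular consequence of one SNV on one gene.

    ``protein_change`` uses X for a stop ("Q->X"); ``cds_notation`` is a
    compact CDS-coordinate description, e.g. "123C>T" for a coding change
    or "465+1G>A" / "262-1G>A" for donor/acceptor splice positions.
    """

    category: str  # nonsense|missense|splice_donor|splice_acceptor|synonymous|intergenic|intronic
    protein_change: Optional[str] = None
    cds_notation: Optional[str] = None


def _cds_sequence(gene: GeneModel, seq: str) -> str:
    s = "".join(seq[a:b] for a, b in gene.exons)
    if gene.strand == "-":
        s = s.translate(_COMPLEMENT)[::-1]
    return s


def annotate_consequence(
    v: VariantCall,
    gene: GeneModel,
    seq: str,
    splice_window: int = 2,
) -> ConsequenceCall:
    """Classify one SNV against one gene model, strand-aware.

    A coding SNV is translated through the standard code (nonsense when
    the new codon is a stop); an intronic position within
    ``splice_window`` bp of an exon junction is a splice-donor or
    -acceptor change in *transcription* orientation. An SNV hitting an
    incomplete trailing codon is reported as missense without a protein
    change.
    """
    pos0 = v.pos - 1
    if not 0 <= pos0 < len(seq):
        raise ConfigurationError(f"position {v.pos} outside the chromosome")
    if not gene.contains(pos0):
        return ConsequenceCall(category="intergenic")

    exons = list(gene.exons)
    minus = gene.strand == "-"
    lengths = [b - a for a, b in exons]

    def cds_index(pos: int, k: int) -> int:
        """0-based CDS coordinate of genomic ``pos`` inside exon k."""
        if not minus:
            return sum(lengths[:k]) + (pos - exons[k][0])
        return sum(lengths[k + 1:]) + (exons[k][1] - 1 - pos)

    ref_t = v.ref.translate(_COMPLEMENT) if minus else v.ref
    alt_t = v.alt.translate(_COMPLEMENT) if minus else v.alt

    for k, (a, b) in enumerate(exons):
        if a <= pos0 < b:
            ci = cds_index(pos0, k)
            cds = _cds_sequence(gene, seq)
            notation = f"{ci + 1}{ref_t}>{alt_t}"
            codon_start = (ci // 3) * 3
            codon = cds[codon_start:codon_start + 3]
            if len(codon) < 3:
                return ConsequenceCall("missense", None, notation)
            mutated = list(codon)
            mutated[ci % 3] = alt_t
            aa_ref = _CODON_TABLE[codon]
            aa_alt = _CODON_TABLE["".join(mutated)]
            if aa_alt == aa_ref:
                cat = "synonymous"
            elif aa_alt == "*":
                cat = "nonsense"
            else:
                cat = "missense"
            show = lambda aa: "X" if aa == "*" else aa
            return ConsequenceCall(cat, f"{show(aa_ref)}->{show(aa_alt)}", notation)

    # intronic: locate the flanking exons
    for k in range(len(exons) - 1):
        left_end = exons[k][1]
        right_start = exons[k + 1][0]
        if left_end <= pos0 < right_start:
            off_left = pos0 - left_end + 1       # 1 = first intron base after left exon
            off_right = right_start - pos0        # 1 = last intron base before right exon
            if not minus:
                if off_left <= splice_window:
                    anchor = cds_index(left_end - 1, k) + 1
                    return ConsequenceCall(
                        "splice_donor", None, f"{anchor}+{off_left}{ref_t}>{alt_t}"
                    )
                if off_right <= splice_window:
                    anchor = cds_index(right_start, k + 1) + 1
                    return ConsequenceCall(
                        "splice_acceptor", None, f"{anchor}-{off_right}{ref_t}>{alt_t}"
                    )
            else:
                # transcription runs right-to-left: the junction at the
                # right exon's start is the donor, the left exon's end the
                # acceptor
                if off_right <= splice_window:
                    anchor = cds_index(right_start, k + 1) + 1
                    return ConsequenceCall(
                        "splice_donor", None, f"{anchor}+{off_right}{ref_t}>{alt_t}"
                    )
                if off_left <= splice_window:
                    anchor = cds_index(left_end - 1, k) + 1
                    return ConsequenceCall(
                        "splice_acceptor", None, f"{anchor}-{off_left}{ref_t}>{alt_t}"
                    )
            return ConsequenceCall("intronic")
    return ConsequenceCall("intronic")  # inside the gene but outside exons/introns


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-gene external evidence flags (tri-state: None = unknown)."""

    gene_id: str
    rnai_lethal: Optional[bool] = None
    known_lethal_allele: Optional[bool] = None
    mmp_clean: bool = True  # no homozygous-viable disruptive allele catalogued


@dataclass(frozen=True)
class Candidate:
    """One surviving SNV attributed to (at most) one gene in one strain."""

    strain_id: str
    variant: VariantCall
    gene_id: Optional[str]
    consequence: ConsequenceCall
    zone_match: Optional[bool] = None  # None = strain has no mapped zone
    tier: Optional[str] = None


def map_to_genes(
    variants: Sequence[VariantCall],
    genome: GenomeModel,
    strain_id: str,
    splice_window: int = 2,
) -> tuple[list[Candidate], list[VariantCall]]:
    """Attribute each surviving variant to the gene containing it.

    Returns (candidates, intergenic bucket); every input variant lands in
    exactly one of the two.
    """
    if genome.seq is None:
        raise ConfigurationError("genome sequence required for annotation")
    candidates, intergenic = [], []
    for v in variants:
        gene = genome.gene_at(v.pos - 1)
        if gene is None:
            intergenic.append(v)
            continue
        csq = annotate_consequence(v, gene, genome.seq, splice_window)
        candidates.append(
            Candidate(strain_id=strain_id, variant=v, gene_id=gene.gene_id, consequence=csq)
        )
    return candidates, intergenic


def screen_by_zone(
    candidates: Sequence[Candidate],
    genome: GenomeModel,
    strain_zone: Mapping[str, str],
) -> list[Candidate]:
    """Flag each candidate by whether it lies in its strain's mapped zone.

    Candidates of strains without a mapped zone keep ``zone_match=None``;
    nothing is deleted — mismatches are flagged for the evidence tier.
    """
    zones = {z.zone_id: z for z in genome.zones}
    out = []
    for c in candidates:
        zid = strain_zone.get(c.strain_id)
        if not zid or zid not in zones:
            out.append(replace(c, zone_match=None))
            continue
        out.append(replace(c, zone_match=zones[zid].contains(c.variant.pos - 1)))
    return out


_TIER_ORDER = {"candidate": 0, "supported": 1, "high": 2}


def integrate_evidence(candidate: Candidate, ev: EvidenceRecord) -> str:
    """Evidence tier of one candidate.

    * ``high``: in the mapped zone, independent lethality support (RNAi or
      known allele), and no viable disruptive allele catalogued.
    * ``supported``: in the mapped zone and no viable disruptive allele.
    * ``candidate``: everything else (zone mismatch or unknown, or a
      catalogued viable nonsense/splice allele caps the tier here).
    """
    zone_ok = candidate.zone_match is True
    phenotype = bool(ev.rnai_lethal) or bool(ev.known_lethal_allele)
    if zone_ok and ev.mmp_clean and phenotype:
        return "high"
    if zone_ok and ev.mmp_clean:
        return "supported"
    return "candidate"


@dataclass
class EssentialGeneCall:
    """A called essential gene: its surviving alleles and best tier."""

    gene_id: str
    alleles: list[tuple[str, VariantCall, ConsequenceCall]]  # (strain_id, ...)
    tier: str = "candidate"
    novel_flag: bool = False

    @property
    def n_alleles(self) -> int:
        return len({(v.pos, v.alt) for _, v, _ in self.alleles})


def group_alleles(
    candidates: Sequence[Candidate],
) -> tuple[list[EssentialGeneCall], dict[str, list[str]]]:
    """Merge candidates sharing a gene into one call per gene.

    Allele identity is (pos, alt); every contributing strain is listed.
    Returns the calls plus a multi-hit report mapping any strain that
    contributed surviving candidates in more than one gene to those gene
    ids (reported, never silently resolved).
    """
    by_gene: dict[str, list[Candidate]] = {}
    strain_genes: dict[str, set[str]] = {}
    for c in candidates:
        if c.gene_id is None:
            continue
        by_gene.setdefault(c.gene_id, []).append(c)
        strain_genes.setdefault(c.strain_id, set()).add(c.gene_id)
    calls = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]
        tier = max((c.tier or "candidate" for c in group), key=_TIER_ORDER.__getitem__)
        calls.append(
            EssentialGeneCall(
                gene_id=gene_id,
                alleles=[(c.strain_id, c.variant, c.consequence) for c in group],
                tier=tier,
            )
        )
    multi_hit = {
        sid: sorted(genes) for sid, genes in strain_genes.items() if len(genes) > 1
    }
    return calls, multi_hit


# ---------------------------------------------------------------------------
# published-catalog fixture (44 genes / 58 alleles)

_CONSERVATION_TOKENS = frozenset("IFMN")


@dataclass(frozen=True)
class Table1Record:
    let_name: str
    gene_name: str
    alleles: tuple[str, ...]
    nt_change: str
    aa_change: str
    pfam: str
    kog: str
    conservation: frozenset[str]  # subset of {I, F, M, N}
    novel_flag: bool

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"{self.let_name}: no alleles")
        if not self.conservation:
            raise ValueError(f"{self.let_name}: empty conservation set")


def packaged_table1_path():
    """Path-like handle to the packaged essential-gene catalog TSV."""
    return resources.files("lethalmap.data") / "table1.tsv"


def parse_table1(path=None) -> list[Table1Record]:
    """Read the essential-gene catalog TSV (the packaged one by default)."""
    src = packaged_table1_path() if path is None else path
    records = []
    with open(src, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            tokens = [t.strip() for t in row["conservation"].split(",") if t.strip()]
            bad = [t for t in tokens if t not in _CONSERVATION_TOKENS]
            if bad:
                raise ValueError(
                    f"row {i} ({row['let_name']}): unknown conservation token(s) {bad}"
                )
            records.append(
                Table1Record(
                    let_name=row["let_name"],
                    gene_name=row["gene"],
                    alleles=tuple(a.strip() for a in row["alleles"].split(",") if a.strip()),
                    nt_change=row["nt_change"],
                    aa_change=row["aa_change"],
                    pfam=row["pfam"],
                    kog=row["kog"],
                    conservation=frozenset(tokens),
                    novel_flag=row["novel"].strip() == "1",
                )
            )
    return records


_T1_COLUMNS = ["let_name", "gene", "alleles", "nt_change", "aa_change", "pfam", "kog", "conservation", "novel"]


def write_table1(records: Sequence[Table1Record], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_T1_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.let_name,
                    r.gene_name,
                    ",".join(r.alleles),
                    r.nt_change,
                    r.aa_change,
                    r.pfam,
                    r.kog,
                    ",".join(sorted(r.conservation, key="IFMN".index)),
                    "1" if r.novel_flag else "0",
                ]
            )


@dataclass(frozen=True)
class Table1Summary:
    n_genes: int
    n_alleles: int
    conservation_counts: Mapping[frozenset, int]
    n_conserved_all: int
    n_novel: int


def summarize_table1(records: Sequence[Table1Record]) -> Table1Summary:
    """Headline counts of the catalog: genes, distinct allele names,
    conservation-pattern breakdown, previously uncharacterized genes."""
    alleles = [a for r in records for a in r.alleles]
    cons = Counter(r.conservation for r in records)
    return Table1Summary(
        n_genes=len(records),
        n_alleles=len(set(alleles)),
        conservation_counts=dict(cons),
        n_conserved_all=cons.get(frozenset("IFMN"), 0),
        n_novel=sum(r.novel_flag for r in records),
    )
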