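"""Consequence annotation, evidence tiers, allele grouping, catalog fixture."""
import dataclasses

import pytest

from conftest import make_variant
from lethalmap.genes import (
    Candidate,
    ConsequenceCall,
    EvidenceRecord,
    annotate_consequence,
    group_alleles,
    integrate_evidence,
    map_to_genes,
    parse_table1,
    screen_by_zone,
    summarize_table1,
    write_table1,
)
from lethalmap.models import GeneModel, GenomeModel, MappingZone
from lethalmap.simulate import CohortConfig, simulate_cohort
from lethalmap.variants import apply_filters, qc_strains
from lethalmap.models import FilterParams

#       0         1         2         3
#       0123456789012345678901234567890123456789
SEQ = "TTTTTATGCAACGGGGTACGTGGGGGGATCCAAGGGTTTTTT".ljust(100, "A")
# exon1 = [5, 14): ATG CAA CGG  -> M Q R
# intron = [14, 26)
# exon2 = [26, 35): GAT CCA AGG -> D P R
PLUS_GENE = GeneModel(
    gene_id="gplus", start=5, end=35, strand="+", exons=((5, 14), (26, 35))
)


class TestConsequencePlusStrand:
    def test_nonsense_q_to_stop(self):
        # CAA -> TAA at CDS position 4 (genomic pos0 8, 1-based 9)
        v = make_variant(pos=9, ref="C", alt="T")
        c = annotate_consequence(v, PLUS_GENE, SEQ)
        assert c.category == "nonsense"
        assert c.protein_change == "Q->X"
        assert c.cds_notation == "4C>T"

    def test_missense(self):
        # CAA -> CGA (Q->R) at CDS position 5
        v = make_variant(pos=10, ref="A", alt="G")
        c = annotate_consequence(v, PLUS_GENE, SEQ)
        assert c.category == "missense" and c.protein_change == "Q->R"

    def test_synonymous_third_position(self):
        # CGG -> CGA, both arginine (CDS position 9)
        v = make_variant(pos=14, ref="G", alt="A")
        c = annotate_consequence(v, PLUS_GENE, SEQ)
        assert c.category == "synonymous" and c.protein_change == "R->R"

    def test_splice_donor_first_intron_base(self):
        # pos0 14 = first intron base after exon1 (CDS length so far = 9)
        v = make_variant(pos=15, ref="T", alt="A")
        c = annotate_consequence(v, PLUS_GENE, SEQ)
        assert c.category == "splice_donor"
        assert c.cds_notation == "9+1T>A"

    def test_splice_acceptor_last_intron_base(self):
        # pos0 25 = last intron base before exon2 (next CDS base = 10)
        v = make_variant(pos=26, ref="G", alt="A")
        c = annotate_consequence(v, PLUS_GENE, SEQ)
        assert c.category == "splice_acceptor"
        assert c.cds_notation == "10-1G>A"

    def test_deep_intronic_and_intergenic(self):
        assert annotate_consequence(make_variant(pos=21, ref="G", alt="A"), PLUS_GENE, SEQ).category == "intronic"
        assert annotate_consequence(make_variant(pos=2, ref="T", alt="A"), PLUS_GENE, SEQ).category == "intergenic"

    def test_out_of_bounds_position_raises(self):
        from lethalmap.models import ConfigurationError

        with pytest.raises(ConfigurationError):
            annotate_consequence(make_variant(pos=5000, ref="A", alt="T"), PLUS_GENE, SEQ)


class TestConsequenceMinusStrand:
    # minus-strand gene on the same layout: CDS read right-to-left
    MINUS_GENE = dataclasses.replace(PLUS_GENE, gene_id="gminus", strand="-")

    def test_coding_change_is_complemented(self):
        # genomic C>T inside exon2 reads as G>A on the transcript
        v = make_variant(pos=30, ref="C", alt="T")
        c = annotate_consequence(v, self.MINUS_GENE, SEQ)
        assert c.category in {"missense", "nonsense", "synonymous"}
        assert "G>A" in c.cds_notation

    def test_donor_acceptor_roles_swap(self):
        # first intron base after exon1 (genomic) is acceptor-side on minus strand
        v = make_variant(pos=15, ref="T", alt="A")
        assert annotate_consequence(v, self.MINUS_GENE, SEQ).category == "splice_acceptor"
        v = make_variant(pos=26, ref="G", alt="A")
        assert annotate_consequence(v, self.MINUS_GENE, SEQ).category == "splice_donor"


ZONE_GENOME = GenomeModel(
    chrom_name="chrI",
    chrom_length=100,
    genes=[PLUS_GENE],
    zones=[MappingZone("z1", 0, 50), MappingZone("z2", 50, 100)],
    balanced_region=(0, 100),
    seq=SEQ,
)


def _candidate(pos, strain="s1"):
    return Candidate(
        strain_id=strain,
        variant=make_variant(pos=pos),
        gene_id="gplus",
        consequence=ConsequenceCall("missense"),
    )


class TestZoneScreen:
    def test_containment_and_boundary(self):
        cands = screen_by_zone(
            [_candidate(50), _candidate(51)], ZONE_GENOME, {"s1": "z1"}
        )
        # 1-based 50 = pos0 49 inside z1=[0,50); 1-based 51 = pos0 50 is not
        assert cands[0].zone_match is True
        assert cands[1].zone_match is False

    def test_unmapped_strain_kept_with_unknown(self):
        (c,) = screen_by_zone([_candidate(10)], ZONE_GENOME, {})
        assert c.zone_match is None

    def test_planted_lethals_all_in_zone(self, genome):
        cohort = simulate_cohort(genome, CohortConfig(seed=11))
        params = FilterParams()
        passing, _ = qc_strains(cohort.strains, cohort.markers, params)
        lethal = {t.strain_id: t.variant_key for t in cohort.lethals}
        for s in passing[:20]:
            surv, _ = apply_filters(s, cohort.background, params, cohort.markers)
            cands, _ = map_to_genes(surv, genome, s.strain_id)
            cands = screen_by_zone(cands, genome, cohort.strain_zone)
            planted = [c for c in cands if c.variant.key == lethal[s.strain_id]]
            assert all(c.zone_match for c in planted)


class TestEvidenceTiers:
    BASE = _candidate(10)

    def _with_zone(self, match):
        return dataclasses.replace(self.BASE, zone_match=match)

    def test_rule_table(self):
        ev = EvidenceRecord("gplus", rnai_lethal=True, mmp_clean=True)
        assert integrate_evidence(self._with_zone(True), ev) == "high"
        ev = EvidenceRecord("gplus", rnai_lethal=False, mmp_clean=True)
        assert integrate_evidence(self._with_zone(True), ev) == "supported"
        # a catalogued homozygous-viable disruptive allele caps the tier
        ev = EvidenceRecord("gplus", rnai_lethal=True, mmp_clean=False)
        assert integrate_evidence(self._with_zone(True), ev) == "candidate"
        assert integrate_evidence(self._with_zone(False), EvidenceRecord("gplus")) == "candidate"

    def test_tier_monotone_in_evidence(self):
        order = {"candidate": 0, "supported": 1, "high": 2}
        for zone in (True, False, None):
            for rnai in (False, True):
                for allele in (False, True):
                    for clean in (False, True):
                        base = integrate_evidence(
                            self._with_zone(zone),
                            EvidenceRecord("g", rnai_lethal=rnai, known_lethal_allele=allele, mmp_clean=clean),
                        )
                        # flipping any single flag positive never lowers the tier
                        for up in (
                            EvidenceRecord("g", rnai_lethal=True, known_lethal_allele=allele, mmp_clean=clean),
                            EvidenceRecord("g", rnai_lethal=rnai, known_lethal_allele=True, mmp_clean=clean),
                            EvidenceRecord("g", rnai_lethal=rnai, known_lethal_allele=allele, mmp_clean=True),
                        ):
                            assert order[integrate_evidence(self._with_zone(zone), up)] >= order[base]


class TestGrouping:
    def test_three_sibling_strains_one_gene(self):
        cands = [
            dataclasses.replace(_candidate(10, strain=s), tier="supported")
            for s in ("h744", "h282", "h89")
        ]
        # distinct alleles at distinct positions
        cands = [
            dataclasses.replace(c, variant=make_variant(pos=p))
            for c, p in zip(cands, (10, 11, 12))
        ]
        calls, multi = group_alleles(cands)
        assert len(calls) == 1
        assert calls[0].n_alleles == 3
        assert multi == {}

    def test_single_candidate(self):
        calls, _ = group_alleles([dataclasses.replace(_candidate(10), tier="high")])
        assert len(calls) == 1 and calls[0].n_alleles == 1 and calls[0].tier == "high"

    def test_multi_hit_strain_flagged(self):
        a = dataclasses.replace(_candidate(10, strain="sX"), gene_id="gene_a")
        b = dataclasses.replace(_candidate(20, strain="sX"), gene_id="gene_b")
        _, multi = group_alleles([a, b])
        assert multi == {"sX": ["gene_a", "gene_b"]}

    def test_shared_allele_count_not_inflated(self):
        # two strains carrying the same (pos, alt) allele -> one allele
        a = _candidate(10, strain="s1")
        b = _candidate(10, strain="s2")
        calls, _ = group_alleles([a, b])
        assert calls[0].n_alleles == 1
        assert len(calls[0].alleles) == 2  # both strains listed


class TestCatalogFixture:
    def test_headline_counts(self):
        s = summarize_table1(parse_table1())
        assert s.n_genes == 44
        assert s.n_alleles == 58
        assert s.n_novel == 6

    def test_conservation_patterns(self):
        s = summarize_table1(parse_table1())
        assert s.conservation_counts[frozenset("FN")] == 3
        assert s.conservation_counts[frozenset("FMN")] == 3
        assert s.conservation_counts[frozenset("IFN")] == 2

    def test_round_trip(self, tmp_path):
        records = parse_table1()
        write_table1(records, tmp_path / "t1.tsv")
        assert parse_table1(tmp_path / "t1.tsv") == records

    def test_malformed_conservation_token_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "let_name\tgene\talleles\tnt_change\taa_change\tpfam\tkog\tconservation\tnovel\n"
            "let-1\tabc-1\th1\tC>T\tQ>X\t.\t.\tI,F,Z\t0\n"
        )
        with pytest.raises(ValueError, match="let-1"):
            parse_table1(p)
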