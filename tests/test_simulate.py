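"""Generator determinism, planted-structure statistics, and IO round-trips."""
import numpy as np
import pytest

from lethalmap import io
from lethalmap.models import ConfigurationError
from lethalmap.simulate import (
    CohortConfig,
    ExpressionConfig,
    GeneratorConfig,
    HiCConfig,
    PPIConfig,
    STAGE_NAMES,
    hic_null_config,
    simulate_cohort,
    simulate_expression,
    simulate_genome,
    simulate_hic,
    simulate_ppi,
)
from lethalmap.variants import qc_strains
from lethalmap.models import FilterParams


class TestGenome:
    def test_single_gene_capacity_one(self):
        cfg = GeneratorConfig(
            chrom_length=10_000, balanced_region=(0, 8_000), n_genes=1,
            group_sizes={"G2": 1}, n_zones=1,
            exons_per_gene=(2, 2), exon_length=(200, 300), intron_length=(50, 100),
        )
        g = simulate_genome(cfg, seed=1)
        assert len(g.genes) == 1
        assert 0 <= g.genes[0].start < g.genes[0].end <= 10_000

    def test_determinism(self):
        a = simulate_genome(GeneratorConfig(), seed=7)
        b = simulate_genome(GeneratorConfig(), seed=7)
        assert a.genes == b.genes and a.zones == b.zones and a.seq == b.seq

    def test_over_capacity_raises(self):
        cfg = GeneratorConfig(
            chrom_length=50_000, balanced_region=(0, 40_000), n_genes=40,
            group_sizes={"G2": 40},
        )
        with pytest.raises(ConfigurationError):
            simulate_genome(cfg, seed=1)

    def test_gene_layout_invariants(self, genome):
        prev_end = -1
        for g in genome.genes:
            assert g.start > prev_end, "genes overlap"
            prev_end = g.end
            assert g.coding_length == sum(e - s for s, e in g.exons)
        # zones tile the balanced region without overlap
        b0, b1 = genome.balanced_region
        edges = [z.start for z in genome.zones] + [genome.zones[-1].end]
        assert edges[0] == b0 and edges[-1] == b1
        assert all(
            genome.zones[i].end == genome.zones[i + 1].start
            for i in range(len(genome.zones) - 1)
        )


class TestCohort:
    def test_determinism(self, genome):
        a = simulate_cohort(genome, CohortConfig(seed=9))
        b = simulate_cohort(genome, CohortConfig(seed=9))
        assert [s.variants for s in a.strains] == [s.variants for s in b.strains]
        assert a.background == b.background

    def test_all_pass_when_no_failures_planted(self, genome):
        c = simulate_cohort(
            genome, CohortConfig(n_strains=20, n_marker_fail=0, n_low_coverage=0, seed=3)
        )
        passing, rej = qc_strains(c.strains, c.markers, FilterParams())
        assert len(passing) == 20 and rej == []

    def test_ratio_law_two_thirds(self, cohort):
        """Mean allele balance over planted lethals ~ 2/3 within 3 SE."""
        lethal_keys = {t.strain_id: t.variant_key for t in cohort.lethals}
        ratios, depth = [], None
        for s in cohort.strains:
            if cohort.intended_verdicts[s.strain_id] != "pass":
                continue
            key = lethal_keys[s.strain_id]
            v = next(x for x in s.variants if x.key == key)
            ratios.append(v.alt_reads / v.total_reads)
            depth = v.total_reads
        p = 2 / 3
        se = np.sqrt(p * (1 - p) / depth) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - p) < 3 * se

    def test_background_shared_identically(self, cohort):
        for s in cohort.strains:
            keys = {v.key for v in s.variants}
            assert cohort.background <= keys

    def test_no_essential_target_raises(self):
        cfg = GeneratorConfig(
            chrom_length=200_000, balanced_region=(0, 100_000), n_genes=5,
            group_sizes={"G4": 5}, n_zones=1,
        )
        g = simulate_genome(cfg, seed=1)
        with pytest.raises(ConfigurationError):
            simulate_cohort(g, CohortConfig(n_strains=2, n_marker_fail=0, n_low_coverage=0, seed=1))


class TestHiC:
    def test_symmetry_and_nonnegative(self, genome):
        m, _, _ = simulate_hic(genome, HiCConfig(seed=4))
        assert np.array_equal(m.counts, m.counts.T)
        assert (m.counts >= 0).all()

    def test_determinism(self, genome):
        a, _, _ = simulate_hic(genome, HiCConfig(seed=4))
        b, _, _ = simulate_hic(genome, HiCConfig(seed=4))
        assert np.array_equal(a.counts, b.counts)

    def test_partial_last_bin_flagged(self, genome):
        m, _, _ = simulate_hic(genome, HiCConfig(bin_size=70_000, seed=4))
        assert m.partial_last_bin
        assert m.bins[-1][1] == genome.chrom_length

    def test_tads_disjoint_sorted(self, genome):
        _, tads, _ = simulate_hic(genome, HiCConfig(seed=4))
        for (s1, e1), (s2, e2) in zip(tads.tads, tads.tads[1:]):
            assert e1 <= s2

    def test_distance_decay(self, genome):
        m, _, _ = simulate_hic(genome, hic_null_config(4))
        n = m.n_bins
        ii, jj = np.triu_indices(n, k=1)
        d = jj - ii
        mean_near = m.counts[ii, jj][d == 2].mean()
        mean_far = m.counts[ii, jj][d == 50].mean()
        assert mean_near / mean_far == pytest.approx(25, rel=0.15)


class TestPPIExpression:
    def test_ppi_clean_edge_list(self, genome):
        edges = simulate_ppi(genome, PPIConfig(seed=5))
        assert all(u != v for u, v in edges)
        assert len(edges) == len({frozenset(e) for e in edges})

    def test_degree_ratio_parameter_error(self):
        with pytest.raises(ConfigurationError):
            PPIConfig(degree_ratio=-1.0)

    def test_null_degree_ratio_close(self, genome):
        edges = simulate_ppi(genome, PPIConfig(degree_ratio=1.0, seed=5))
        deg = {}
        for u, v in edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        e = [deg.get(g.gene_id, 0) for g in genome.genes if g.essential]
        n = [deg.get(g.gene_id, 0) for g in genome.genes if not g.essential]
        assert abs(np.mean(e) - np.mean(n)) < 1.0

    def test_expression_shape_and_nonnegative(self, genome):
        raw, libs, truth = simulate_expression(genome, ExpressionConfig(seed=6))
        assert list(raw.columns) == list(STAGE_NAMES) and len(raw.columns) == 23
        assert (raw.to_numpy() >= 0).all()
        assert set(truth) == {g.gene_id for g in genome.genes}

    def test_early_module_peaks_in_embryo_stages(self, genome):
        cfg = ExpressionConfig(seed=6)
        raw, _, truth = simulate_expression(genome, cfg)
        early = [g for g, m in truth.items() if cfg.module_peaks[m] < 6]
        peaks = raw.loc[early].to_numpy().argmax(axis=1)
        assert (peaks < 18).mean() > 0.99


class TestRoundTrips:
    def test_vcf_round_trip(self, genome, cohort, tmp_path):
        s = cohort.strains[0]
        p = tmp_path / "s.vcf"
        io.write_strain_vcf(s, p, genome.chrom_name, genome.chrom_length)
        back = io.read_strain_vcf(p)
        assert back.strain_id == s.strain_id
        assert back.mean_depth == s.mean_depth
        assert back.variants == s.variants

    def test_genes_round_trip(self, genome, tmp_path):
        p = tmp_path / "genes.tsv"
        io.write_genes(genome, p)
        assert io.read_genes(p) == genome.genes

    def test_zone_marker_background_round_trips(self, genome, cohort, tmp_path):
        io.write_zones(genome.zones, tmp_path / "z.tsv")
        assert io.read_zones(tmp_path / "z.tsv") == genome.zones
        io.write_markers(cohort.markers, tmp_path / "m.tsv")
        assert io.read_markers(tmp_path / "m.tsv") == cohort.markers
        io.write_background(cohort.background, tmp_path / "b.tsv")
        assert io.read_background(tmp_path / "b.tsv") == cohort.background

    def test_hic_tad_round_trips(self, genome, tmp_path):
        m, tads, _ = simulate_hic(genome, HiCConfig(seed=4))
        io.write_contact_matrix(m, tmp_path / "p.tsv", tmp_path / "b.bed")
        back = io.read_contact_matrix(tmp_path / "p.tsv", tmp_path / "b.bed")
        assert back.bins == m.bins and np.array_equal(back.counts, m.counts)
        io.write_tads(tads, tmp_path / "t.bed", genome.chrom_name)
        assert io.read_tads(tmp_path / "t.bed", genome.chrom_length).tads == tads.tads

    def test_ppi_expression_round_trips(self, genome, tmp_path):
        edges = simulate_ppi(genome, PPIConfig(seed=5))
        io.write_ppi(edges, tmp_path / "ppi.tsv")
        assert io.read_ppi(tmp_path / "ppi.tsv") == edges
        raw, _, _ = simulate_expression(genome, ExpressionConfig(seed=6))
        io.write_expression(raw, tmp_path / "e.tsv")
        assert io.read_expression(tmp_path / "e.tsv").equals(raw)
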