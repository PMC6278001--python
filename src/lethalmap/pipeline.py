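"""End-to-end orchestration from a single YAML/JSON config.

``run_all`` executes: simulate (optional) -> strain QC -> variant
filtering -> gene calling -> Hi-C locus clustering -> TAD-boundary
enrichment -> PPI degree and expression-module comparisons, writing
audit TSVs plus a JSON manifest of parameters, seeds and per-stage
record counts. Re-running an identical config reproduces byte-identical
TSV outputs (the manifest differs only in its timestamp).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__, io
from .genes import (
    EvidenceRecord,
    group_alleles,
    integrate_evidence,
    map_to_genes,
    screen_by_zone,
)
from .hic import (
    call_significant,
    expected_by_distance,
    gene_contact_frequency,
    group_loci,
    ice_normalize,
)
from .models import ConfigurationError, FilterParams
from .netexpr import center_rows, cluster_modules, normalize_expression, ppi_degree
from .simulate import (
    CohortConfig,
    ExpressionConfig,
    GeneratorConfig,
    HiCConfig,
    PPIConfig,
    simulate_cohort,
    simulate_expression,
    simulate_genome,
    simulate_hic,
    simulate_ppi,
)
from .stats import compare_groups
from .variants import apply_filters, qc_strains

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "RunConfig", "paper_default_config", "load_config", "run_all"]

GROUPS = ("G1", "G2", "G3", "G4")


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the downstream analyses (defaults = the screen's values)."""

    hic_min_count: int = 15
    hic_alpha: float = 0.01
    hic_min_partners: int = 2
    hic_min_occupancy: int = 30
    hic_min_separation: int = 2
    tad_flank: int = 0
    tad_mode: str = "body"
    expr_k_modules: int = 8
    splice_window: int = 2


_SECTION_TYPES = {
    "genome": GeneratorConfig,
    "cohort": CohortConfig,
    "hic": HiCConfig,
    "ppi": PPIConfig,
    "expression": ExpressionConfig,
    "filters": FilterParams,
    "analysis": AnalysisParams,
}


@dataclass
class RunConfig:
    seed: int
    outdir: str
    genome: GeneratorConfig
    cohort: CohortConfig
    hic: HiCConfig
    ppi: PPIConfig
    expression: ExpressionConfig
    filters: FilterParams
    analysis: AnalysisParams


def paper_default_config(seed: int = 0, outdir: str = "lethalmap_out") -> dict:
    """The preset embedding every screen constant: 0.40-0.90 allele-balance
    band, 8 alt reads, 8X coverage floor, 130/23/4 cohort at 23X, 50-kb
    bins, 15-count floor, alpha 0.01, 2 partners."""
    return {"seed": seed, "outdir": outdir}


def _build_section(name: str, cls, values: Mapping[str, Any], seed: Optional[int]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigurationError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    kwargs = dict(values)
    if "balanced_region" in kwargs:
        kwargs["balanced_region"] = tuple(kwargs["balanced_region"])
    if "seed" in known and "seed" not in kwargs and seed is not None:
        kwargs["seed"] = seed
    return cls(**kwargs)


def load_config(raw: Mapping[str, Any], seed_override: Optional[int] = None) -> RunConfig:
    """Validate a raw config mapping; unknown keys are rejected outright."""
    top_known = {"seed", "outdir"} | set(_SECTION_TYPES)
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    seed = int(seed_override if seed_override is not None else raw.get("seed", 0))
    # derive independent child seeds for each stochastic stage
    child = np.random.SeedSequence(seed).spawn(4)
    child_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in child]
    sections = {}
    stage_seed = {"cohort": child_seeds[0], "hic": child_seeds[1],
                  "ppi": child_seeds[2], "expression": child_seeds[3]}
    for name, cls in _SECTION_TYPES.items():
        sections[name] = _build_section(
            name, cls, raw.get(name, {}) or {}, stage_seed.get(name)
        )
    return RunConfig(
        seed=seed,
        outdir=str(raw.get("outdir", "lethalmap_out")),
        **sections,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    out = Path(cfg.outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "params": {
            name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTION_TYPES
        },
        "stages": {},
    }

    # --- simulate ---------------------------------------------------------
    genome = simulate_genome(cfg.genome, seed=cfg.seed)
    cohort = simulate_cohort(genome, cfg.cohort)
    matrix, tadset, planted_pairs = simulate_hic(genome, cfg.hic)
    edges = simulate_ppi(genome, cfg.ppi)
    raw_expr, libs, module_truth = simulate_expression(genome, cfg.expression)

    io.write_genes(genome, out / "inputs" / "genes.tsv")
    io.write_zones(genome.zones, out / "inputs" / "zones.tsv")
    io.write_markers(cohort.markers, out / "inputs" / "markers.tsv")
    io.write_background(cohort.background, out / "inputs" / "background.tsv")
    io.write_contact_matrix(matrix, out / "inputs" / "hic_pairs.tsv", out / "inputs" / "hic_bins.bed")
    io.write_tads(tadset, out / "inputs" / "tads.bed", genome.chrom_name)
    io.write_ppi(edges, out / "inputs" / "ppi.tsv")
    io.write_expression(raw_expr, out / "inputs" / "expression_counts.tsv")
    vcf_dir = out / "inputs" / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for s in cohort.strains:
        io.write_strain_vcf(s, vcf_dir / f"{s.strain_id}.vcf", genome.chrom_name, genome.chrom_length)
    manifest["stages"]["simulate"] = {
        "n_strains": len(cohort.strains),
        "n_genes": len(genome.genes),
        "n_hic_bins": matrix.n_bins,
        "n_ppi_edges": len(edges),
        "n_planted_hic_pairs": len(planted_pairs),
    }

    # --- strain QC --------------------------------------------------------
    passing, rejections = qc_strains(cohort.strains, cohort.markers, cfg.filters)
    _write_tsv(
        pd.DataFrame(
            [(r.strain_id, r.reason, r.detail) for r in rejections],
            columns=["strain_id", "reason", "detail"],
        ),
        out / "qc_rejections.tsv",
    )
    manifest["stages"]["qc"] = {
        "n_input": len(cohort.strains),
        "n_pass": len(passing),
        "n_fail_marker": sum(r.reason == "fail_marker" for r in rejections),
        "n_fail_coverage": sum(r.reason == "fail_coverage" for r in rejections),
    }

    # --- variant filtering ------------------------------------------------
    audit_rows = []
    surviving_by_strain = {}
    for s in passing:
        surv, audits = apply_filters(s, cohort.background, cfg.filters, cohort.markers)
        surviving_by_strain[s.strain_id] = surv
        for a in audits:
            audit_rows.append(
                (
                    s.strain_id, a.variant.chrom, a.variant.pos, a.variant.ref,
                    a.variant.alt, round(a.ratio, 6), int(a.in_band),
                    int(a.read_support), int(a.not_background), int(a.survives),
                )
            )
    _write_tsv(
        pd.DataFrame(
            audit_rows,
            columns=[
                "strain_id", "chrom", "pos", "ref", "alt", "ratio",
                "in_band", "read_support", "not_background", "survives",
            ],
        ),
        out / "variant_audit.tsv",
    )
    # marker loci are engineered mutations, not candidates, so the audited
    # count excludes them
    n_out = sum(len(v) for v in surviving_by_strain.values())
    manifest["stages"]["variants"] = {"n_input": len(audit_rows), "n_surviving": n_out}

    # --- gene calling -----------------------------------------------------
    rng_ev = np.random.default_rng(cfg.seed + 1)
    evidence = {
        g.gene_id: EvidenceRecord(
            gene_id=g.gene_id,
            rnai_lethal=bool(g.essential and rng_ev.random() < 0.8),
            known_lethal_allele=bool(g.essential and rng_ev.random() < 0.5),
            mmp_clean=g.essential or rng_ev.random() < 0.3,
        )
        for g in genome.genes
    }
    candidates = []
    n_intergenic = 0
    for sid, variants in surviving_by_strain.items():
        cands, inter = map_to_genes(variants, genome, sid, cfg.analysis.splice_window)
        n_intergenic += len(inter)
        candidates.extend(cands)
    candidates = screen_by_zone(candidates, genome, cohort.strain_zone)
    candidates = [
        dataclasses.replace(
            c, tier=integrate_evidence(c, evidence.get(c.gene_id) or EvidenceRecord(c.gene_id))
        )
        for c in candidates
    ]
    calls, multi_hit = group_alleles(candidates)
    _write_tsv(
        pd.DataFrame(
            [
                (
                    c.gene_id, c.n_alleles, c.tier,
                    ";".join(sorted({sid for sid, _, _ in c.alleles})),
                    ";".join(f"{v.pos}{v.ref}>{v.alt}" for _, v, _ in c.alleles),
                    ";".join(q.category for _, _, q in c.alleles),
                )
                for c in calls
            ],
            columns=["gene_id", "n_alleles", "tier", "strains", "alleles", "consequences"],
        ),
        out / "gene_calls.tsv",
    )
    manifest["stages"]["gene_calling"] = {
        "n_candidates": len(candidates),
        "n_intergenic": n_intergenic,
        "n_gene_calls": len(calls),
        "n_multi_hit_strains": len(multi_hit),
    }

    # --- Hi-C clustering --------------------------------------------------
    ice = ice_normalize(matrix)
    expected = expected_by_distance(
        matrix, ice, min_occupancy=cfg.analysis.hic_min_occupancy,
        min_separation=cfg.analysis.hic_min_separation,
    )
    sig = call_significant(
        matrix, expected, min_count=cfg.analysis.hic_min_count, alpha=cfg.analysis.hic_alpha
    )
    groups = group_loci(sig, min_partners=cfg.analysis.hic_min_partners)
    freq = gene_contact_frequency(groups, genome.genes, matrix.bins)
    _write_tsv(
        pd.DataFrame(
            [(s.locus_i, s.locus_j, s.raw_count, s.p_value) for s in sig],
            columns=["locus_i", "locus_j", "raw_count", "p_value"],
        ),
        out / "hic_significant_pairs.tsv",
    )
    _write_tsv(
        pd.DataFrame(sorted(freq.items()), columns=["gene_id", "contact_frequency"]),
        out / "gene_contact_frequency.tsv",
    )
    manifest["stages"]["hic"] = {
        "ice_converged": ice.converged,
        "n_significant": len(sig),
        "n_groups": len(groups),
    }

    # --- group comparisons (contact frequency, PPI degree) ----------------
    from .tads import boundary_enrichment, classify_gene

    by_group = {lab: [g for g in genome.genes if g.group == lab] for lab in GROUPS}

    def _compare_table(values: Mapping[str, float], fname: str) -> None:
        rows = []
        for i, a in enumerate(GROUPS):
            for b in GROUPS[i + 1:]:
                va = [values[g.gene_id] for g in by_group[a]]
                vb = [values[g.gene_id] for g in by_group[b]]
                if not va or not vb:
                    continue
                c = compare_groups(a, va, b, vb)
                rows.append(
                    (a, b, c.n_a, c.n_b, round(c.mean_a, 4), round(c.mean_b, 4),
                     c.levene_p, c.ranksum_p)
                )
        _write_tsv(
            pd.DataFrame(
                rows,
                columns=["group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b",
                         "levene_p", "ranksum_p"],
            ),
            out / fname,
        )

    _compare_table(freq, "contact_frequency_comparisons.tsv")

    # --- TAD boundary enrichment ------------------------------------------
    cls_rows = [
        (g.gene_id, g.group, classify_gene(g, tadset, cfg.analysis.tad_flank, cfg.analysis.tad_mode))
        for g in genome.genes
    ]
    _write_tsv(
        pd.DataFrame(cls_rows, columns=["gene_id", "group", "tad_class"]),
        out / "tad_classification.tsv",
    )
    enr_rows = []
    for i, a in enumerate(GROUPS):
        for b in GROUPS[i + 1:]:
            if not by_group[a] or not by_group[b]:
                continue
            e = boundary_enrichment(
                by_group[a], by_group[b], tadset,
                flank=cfg.analysis.tad_flank, mode=cfg.analysis.tad_mode,
                label_a=a, label_b=b,
            )
            (ba, ia), (bb, ib) = e.table
            enr_rows.append((a, b, ba, ia, bb, ib, e.odds_ratio, e.p_value))
    _write_tsv(
        pd.DataFrame(
            enr_rows,
            columns=["group_a", "group_b", "boundary_a", "interior_a",
                     "boundary_b", "interior_b", "odds_ratio", "fisher_p"],
        ),
        out / "tad_enrichment.tsv",
    )
    manifest["stages"]["tad"] = {
        "n_tads": len(tadset.tads),
        "n_boundary_genes": sum(1 for _, _, c in cls_rows if c == "boundary"),
    }

    # --- PPI degree -------------------------------------------------------
    degree = ppi_degree(edges, universe=[g.gene_id for g in genome.genes])
    _write_tsv(
        pd.DataFrame(sorted(degree.items()), columns=["gene_id", "degree"]),
        out / "ppi_degree.tsv",
    )
    _compare_table(degree, "ppi_degree_comparisons.tsv")
    manifest["stages"]["ppi"] = {
        "n_edges": len(edges),
        "n_genes_in_network": sum(1 for d in degree.values() if d > 0),
    }

    # --- expression modules -----------------------------------------------
    coding = {g.gene_id: g.coding_length for g in genome.genes}
    norm = normalize_expression(raw_expr, coding, libs)
    centered = center_rows(norm)
    modules = cluster_modules(centered, k=cfg.analysis.expr_k_modules)
    mod_rows = [
        (m.module_id, gid, m.peak_stage, m.peak_phase)
        for m in modules
        for gid in m.members
    ]
    _write_tsv(
        pd.DataFrame(mod_rows, columns=["module_id", "gene_id", "peak_stage", "peak_phase"]),
        out / "expression_modules.tsv",
    )
    phase_of = {gid: phase for _, gid, _, phase in mod_rows}
    essential_ids = [g.gene_id for g in genome.genes if g.essential]
    early_frac = float(
        np.mean([phase_of[g] == "early-embryonic" for g in essential_ids])
    ) if essential_ids else float("nan")
    manifest["stages"]["expression"] = {
        "n_modules": len(modules),
        "essential_early_fraction": round(early_frac, 4),
    }

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
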