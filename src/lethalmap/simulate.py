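"""Synthetic data with planted ground truth.

Generates everything the pipeline consumes: a single chromosome with gene
models, mapping zones and a balanced (duplication-covered) region; a
cohort of mutant strains each carrying one planted lethal SNV at a 2/3
allele balance plus two marker mutations; a Hi-C contact map with
distance decay, planted domains and planted long-range contacts; a PPI
edge list with an essentiality degree bias; and a stage-course expression
count matrix with stage-peaked modules.

Every generator takes an explicit seed (directly or in its config) and is
deterministic given it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .models import (
    ConfigurationError,
    FilterParams,
    GeneModel,
    GenomeModel,
    MappingZone,
    MarkerDef,
    StrainRecord,
    VariantCall,
)

__all__ = [
    "GeneratorConfig",
    "CohortConfig",
    "HiCConfig",
    "PPIConfig",
    "ExpressionConfig",
    "Cohort",
    "PlantedLethal",
    "STAGE_NAMES",
    "simulate_genome",
    "default_markers",
    "simulate_cohort",
    "simulate_hic",
    "hic_null_config",
    "hic_cluster_scenario",
    "simulate_ppi",
    "simulate_expression",
]

BASES = "ACGT"

#: The 23 developmental stages of the expression course: 18 embryo time
#: points, four larval stages, young adult.
STAGE_NAMES: tuple[str, ...] = tuple(
    [f"embryo_{i:02d}" for i in range(1, 19)] + ["L1", "L2", "L3", "L4", "young_adult"]
)


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GeneratorConfig:
    """Layout of the synthetic chromosome.

    Defaults emulate the left arm of C. elegans chromosome I: a ~7.3 Mb
    region whose first 5.4 Mb are covered by a rescuing duplication. Gene
    counts are desk-scale; the four essentiality classes keep the real
    catalog's strong skew toward non-essential genes (G1 screen-derived
    essential and G2 balanced-region essential genes are placed inside the
    balanced region).
    """

    chrom_name: str = "chrI"
    chrom_length: int = 7_300_000
    balanced_region: tuple[int, int] = (0, 5_400_000)
    n_genes: int = 400
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"G1": 8, "G2": 40, "G3": 80, "G4": 272}
    )
    n_zones: int = 6
    exons_per_gene: tuple[int, int] = (2, 4)      # inclusive range
    exon_length: tuple[int, int] = (150, 600)     # inclusive range
    intron_length: tuple[int, int] = (50, 300)    # inclusive range

    def __post_init__(self) -> None:
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ConfigurationError("group sizes exceed n_genes")
        b0, b1 = self.balanced_region
        if not 0 <= b0 < b1 <= self.chrom_length:
            raise ConfigurationError("balanced_region outside chromosome")


def _gene_structure(rng: np.random.Generator, cfg: GeneratorConfig):
    """Draw one gene's exon layout relative to its own start (offset 0)."""
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    offset = 0
    exons = []
    for i in range(n_ex):
        if i > 0:
            offset += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        ln = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        exons.append((offset, offset + ln))
        offset += ln
    return exons, offset  # offset == gene span


def simulate_genome(config: GeneratorConfig, seed: int) -> GenomeModel:
    """Lay out non-overlapping genes on one chromosome, assign essentiality
    groups and mapping zones, and synthesize a reference sequence.

    Raises :class:`ConfigurationError` when the requested genes cannot fit.
    """
    rng = np.random.default_rng(seed)
    b0, b1 = config.balanced_region

    # group labels: G1/G2 must sit in the balanced region
    labels = []
    for grp, n in config.group_sizes.items():
        labels += [grp] * n
    labels += ["none"] * (config.n_genes - len(labels))

    structures = [_gene_structure(rng, config) for _ in range(config.n_genes)]
    spans = [sp for _, sp in structures]

    balanced_idx = [i for i, lab in enumerate(labels) if lab in ("G1", "G2")]
    other_idx = [i for i in range(config.n_genes) if labels[i] not in ("G1", "G2")]

    def _place(indices: list[int], lo: int, hi: int) -> dict[int, int]:
        """Place genes at non-overlapping random starts in [lo, hi)."""
        total = sum(spans[i] + 1 for i in indices)
        free = (hi - lo) - total
        if free < 0:
            raise ConfigurationError(
                f"cannot fit {len(indices)} genes (total span {total}) into "
                f"{hi - lo} bp"
            )
        # random gaps between consecutive genes (order = shuffled indices)
        order = list(indices)
        rng.shuffle(order)
        cuts = np.sort(rng.integers(0, free + 1, size=len(order)))
        starts = {}
        pos = lo
        prev_cut = 0
        for i, cut in zip(order, cuts):
            pos += int(cut - prev_cut)
            prev_cut = int(cut)
            starts[i] = pos
            pos += spans[i] + 1
        return starts

    starts: dict[int, int] = {}
    starts.update(_place(balanced_idx, b0, b1))
    # remaining genes go anywhere; to keep placement simple and overlap-free,
    # restrict them to the unbalanced tail when it is large enough, otherwise
    # interleave everything in one pass over the whole chromosome.
    tail = config.chrom_length - b1
    if tail >= sum(spans[i] + 1 for i in other_idx):
        starts.update(_place(other_idx, b1, config.chrom_length))
    else:
        starts = _place(list(range(config.n_genes)), 0, config.chrom_length)

    zone_width = math.ceil((b1 - b0) / config.n_zones)
    zones = [
        MappingZone(f"zone_{k + 1}", b0 + k * zone_width, min(b0 + (k + 1) * zone_width, b1))
        for k in range(config.n_zones)
    ]

    genes = []
    for i in sorted(range(config.n_genes), key=lambda i: starts[i]):
        s = starts[i]
        exon_offsets, span = structures[i]
        lab = labels[i]
        mid = s + span // 2
        zone = next((z.zone_id for z in zones if z.contains(mid)), None)
        genes.append(
            GeneModel(
                gene_id=f"gene_{i + 1:04d}",
                start=s,
                end=s + span,
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple((s + a, s + b) for a, b in exon_offsets),
                essential=lab in ("G1", "G2", "G3"),
                group=lab,
                zone_id=zone,
            )
        )

    seq_idx = rng.integers(0, 4, size=config.chrom_length)
    seq = np.frombuffer(b"ACGT", dtype="S1")[seq_idx].tobytes().decode()

    return GenomeModel(
        chrom_name=config.chrom_name,
        chrom_length=config.chrom_length,
        genes=genes,
        zones=zones,
        balanced_region=config.balanced_region,
        seq=seq,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortConfig:
    """Mutant-cohort composition.

    Defaults mirror the screen this emulates: 130 sequenced strains, 23
    lacking the expected marker mutations, 4 sequenced below the 8X
    coverage floor, ~23X mean depth elsewhere.
    """

    n_strains: int = 130
    n_marker_fail: int = 23
    n_low_coverage: int = 4
    depth_mean: int = 23
    background_variant_count: int = 60
    noise_variant_rate: float = 0.0  # per bp per strain
    shared_allele_rate: float = 0.2  # chance a strain reuses an existing allele
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_marker_fail + self.n_low_coverage > self.n_strains:
            raise ConfigurationError("more failing strains than strains")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")


@dataclass(frozen=True)
class PlantedLethal:
    strain_id: str
    gene_id: str
    zone_id: Optional[str]
    variant_key: tuple[str, int, str]  # (chrom, 1-based pos, alt)


@dataclass
class Cohort:
    """Generated strains plus the planted ground truth."""

    strains: list[StrainRecord]
    markers: list[MarkerDef]
    background: set[tuple[str, int, str]]
    lethals: list[PlantedLethal]            # one per strain
    intended_verdicts: dict[str, str]       # strain_id -> pass/fail_marker/fail_coverage
    strain_zone: dict[str, str]             # mapped zone per strain (ground truth)


def default_markers(genome: GenomeModel) -> list[MarkerDef]:
    """The two engineered marker loci: one inside the balanced region
    (expected allele balance 2/3) and one outside it (expected 1.0)."""
    b0, b1 = genome.balanced_region
    p_bal = (b0 + b1) // 2
    p_unbal = b1 + (genome.chrom_length - b1) // 2
    assert genome.seq is not None
    refs = genome.seq[p_bal], genome.seq[p_unbal]
    alts = [BASES[(BASES.index(r) + 1) % 4] for r in refs]
    return [
        MarkerDef("dpy_marker", genome.chrom_name, p_bal + 1, refs[0], alts[0], 2 / 3, True),
        MarkerDef("unc_marker", genome.chrom_name, p_unbal + 1, refs[1], alts[1], 1.0, False),
    ]


def _split_strands(rng: np.random.Generator, n: int) -> tuple[int, int]:
    fwd = int(rng.binomial(n, 0.5)) if n > 0 else 0
    return fwd, n - fwd


def _make_call(
    rng: np.random.Generator,
    chrom: str,
    pos0: int,
    ref: str,
    alt: str,
    depth: int,
    ratio: float,
    condition_band: Optional[tuple[float, float]] = None,
) -> VariantCall:
    """Draw strand-split read counts for a site at the given allele balance.

    With ``condition_band`` the alt count is rejection-sampled until the
    observed ratio lies in the band (used for marker loci, whose planted
    QC outcome must be realized, not merely expected)."""
    for _ in range(10_000):
        k = int(rng.binomial(depth, ratio))
        if condition_band is None:
            break
        if depth > 0 and condition_band[0] <= k / depth <= condition_band[1]:
            break
    else:  # pragma: no cover - band always has positive mass at our depths
        raise ConfigurationError("marker conditioning failed")
    if k == 0 and depth == 0:
        k, depth = 1, 1
    if k == 0 and ratio >= 1.0:
        k = depth
    alt_f, alt_r = _split_strands(rng, k)
    ref_f, ref_r = _split_strands(rng, depth - k)
    if k + (depth - k) == 0:
        ref_f = 1
    return VariantCall(chrom, pos0 + 1, ref, alt, alt_f, alt_r, ref_f, ref_r)


def simulate_cohort(genome: GenomeModel, cfg: CohortConfig) -> Cohort:
    """Generate the mutant cohort.

    Each strain carries: the two marker mutations (omitted in the
    ``n_marker_fail`` strains designated to fail the identity check), one
    planted lethal SNV in an essential balanced-region gene at allele
    balance 2/3, the shared background variant set, and optional noise
    variants. ``n_low_coverage`` strains are sequenced below 8X but retain
    valid markers, so they fail on coverage alone.
    """
    if genome.seq is None:
        raise ConfigurationError("genome must carry a sequence")
    rng = np.random.default_rng(cfg.seed)
    chrom = genome.chrom_name
    b0, b1 = genome.balanced_region
    targets = [
        g for g in genome.genes if g.essential and b0 <= g.start and g.end <= b1
    ]
    if not targets:
        raise ConfigurationError("no essential gene inside the balanced region")

    markers = default_markers(genome)
    marker_pos0 = {m.pos - 1 for m in markers}

    # shared background set (starting-strain variants vs the reference)
    used = set(marker_pos0)
    background: list[tuple[int, str, str, float]] = []  # pos0, ref, alt, ratio
    while len(background) < cfg.background_variant_count:
        p = int(rng.integers(0, genome.chrom_length))
        if p in used:
            continue
        used.add(p)
        ref = genome.seq[p]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        ratio = 0.5 if rng.random() < 0.5 else 1.0
        background.append((p, ref, alt, ratio))
    background_keys = {(chrom, p + 1, alt) for p, _, alt, _ in background}

    # strain statuses, shuffled so failures are not a prefix
    statuses = (
        ["fail_marker"] * cfg.n_marker_fail
        + ["fail_coverage"] * cfg.n_low_coverage
        + ["pass"] * (cfg.n_strains - cfg.n_marker_fail - cfg.n_low_coverage)
    )
    rng.shuffle(statuses)

    band = (FilterParams().ratio_low, FilterParams().ratio_high)
    allele_pool: list[tuple[GeneModel, int, str, str]] = []  # reusable planted alleles

    strains: list[StrainRecord] = []
    lethals: list[PlantedLethal] = []
    verdicts: dict[str, str] = {}
    strain_zone: dict[str, str] = {}

    for i, status in enumerate(statuses):
        sid = f"strain_{i + 1:03d}"
        depth = (
            int(rng.integers(3, 8))
            if status == "fail_coverage"
            else cfg.depth_mean
        )
        calls: list[VariantCall] = []

        # markers
        for m in markers:
            if status == "fail_marker" and not m.balanced:
                continue  # the identity-check mutation is simply absent
            window = band if m.balanced else (band[1], 1.0)
            calls.append(
                _make_call(
                    rng, chrom, m.pos - 1, m.ref, m.alt, depth, m.expected_ratio,
                    condition_band=window,
                )
            )

        # planted lethal: reuse an existing allele (sibling strains) or mint one
        if allele_pool and rng.random() < cfg.shared_allele_rate:
            gene, pos0, ref, alt = allele_pool[int(rng.integers(len(allele_pool)))]
        else:
            gene = targets[int(rng.integers(len(targets)))]
            while True:
                ex = gene.exons[int(rng.integers(len(gene.exons)))]
                pos0 = int(rng.integers(ex[0], ex[1]))
                if pos0 not in used:
                    break
            used.add(pos0)
            ref = genome.seq[pos0]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            allele_pool.append((gene, pos0, ref, alt))
        calls.append(_make_call(rng, chrom, pos0, ref, alt, depth, 2 / 3))
        lethals.append(PlantedLethal(sid, gene.gene_id, gene.zone_id, (chrom, pos0 + 1, alt)))
        strain_zone[sid] = gene.zone_id or ""

        # shared background variants, counts redrawn per strain
        for p, ref_b, alt_b, ratio in background:
            calls.append(_make_call(rng, chrom, p, ref_b, alt_b, depth, ratio))

        # optional noise variants at arbitrary allele balance
        n_noise = int(rng.poisson(cfg.noise_variant_rate * genome.chrom_length))
        for _ in range(n_noise):
            p = int(rng.integers(0, genome.chrom_length))
            if p in used:
                continue
            ref_n = genome.seq[p]
            alt_n = BASES[(BASES.index(ref_n) + int(rng.integers(1, 4))) % 4]
            calls.append(
                _make_call(rng, chrom, p, ref_n, alt_n, depth, float(rng.uniform(0.05, 1.0)))
            )

        calls.sort(key=lambda v: v.pos)
        strains.append(StrainRecord(strain_id=sid, variants=calls, mean_depth=float(depth)))
        verdicts[sid] = status

    return Cohort(
        strains=strains,
        markers=markers,
        background=background_keys,
        lethals=lethals,
        intended_verdicts=verdicts,
        strain_zone=strain_zone,
    )


# ---------------------------------------------------------------------------
# Hi-C


@dataclass(frozen=True)
class HiCConfig:
    """Contact-map generator settings.

    Expected counts decay as (bin distance)^-alpha scaled by ``intensity``
    (chosen so that even the longest-range pair expects well over the
    15-count eligibility floor). Pairs within a planted domain are
    multiplied by ``tad_enrichment``; a clique of long-range pairs among
    bins holding genes of ``plant_on_group`` is multiplied by
    ``planted_fold``. Set ``tad_enrichment=1`` and ``n_planted_bins=0``
    for a pure-decay null map.
    """

    bin_size: int = 50_000
    alpha: float = 1.0
    intensity: float = 4_500.0
    tad_size: int = 250_000
    tad_gap: int = 10_000
    tad_enrichment: float = 3.0
    n_planted_bins: Optional[int] = None  # None = every bin holding a plant_on_group gene
    planted_fold: float = 10.0
    plant_on_group: str = "G2"
    seed: int = 0


def hic_null_config(seed: int, **kw) -> "HiCConfig":
    """Pure distance-decay map: no domain enrichment, no planted pairs.

    The calibration scenario — every significant call on it is a false
    positive."""
    return HiCConfig(tad_enrichment=1.0, n_planted_bins=0, seed=seed, **kw)


def hic_cluster_scenario(seed: int, **kw) -> "HiCConfig":
    """The planted gene-cluster scenario: a long-range contact clique
    among bins holding balanced-region essential (G2) genes on an
    otherwise decay-only background.

    Domain-scale enrichment is deliberately off here: at these map sizes
    domain cliques plus the test's nominal false-positive rate percolate
    into one giant locus group under union-merging, which erases group
    membership as a signal; the clique-on-null design isolates the planted
    clustering being recovered."""
    return HiCConfig(tad_enrichment=1.0, seed=seed, **kw)


@dataclass
class TADSet:
    """Sorted, disjoint self-interacting domains on one chromosome."""

    tads: list[tuple[int, int]]
    chrom_length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.tads:
            if s >= e:
                raise ConfigurationError(f"empty TAD [{s},{e})")
            if s < prev_end:
                raise ConfigurationError("TADs overlap or are unsorted")
            prev_end = e


def _plant_tads(genome: GenomeModel, cfg: HiCConfig, rng: np.random.Generator) -> TADSet:
    """Tile the chromosome with domains separated by small gaps, nudging
    each gap so it avoids essential-gene bodies where possible (the planted
    ground truth: essential genes live inside domains, not at boundaries)."""
    essential = [(g.start, g.end) for g in genome.genes if g.essential]

    def gap_clear(s: int, e: int) -> bool:
        return not any(gs < e and s < ge for gs, ge in essential)

    tads: list[tuple[int, int]] = []
    pos = 0
    while pos + cfg.tad_size + cfg.tad_gap <= genome.chrom_length:
        end = pos + cfg.tad_size + int(rng.integers(-cfg.tad_size // 5, cfg.tad_size // 5 + 1))
        end = min(end, genome.chrom_length - cfg.tad_gap)
        # nudge the gap [end, end+gap) off essential genes
        for shift in (0, 1, -1, 2, -2, 3, -3, 4, -4, 5, -5):
            cand = end + shift * cfg.tad_gap
            if cand <= pos or cand + cfg.tad_gap > genome.chrom_length:
                continue
            if gap_clear(cand, cand + cfg.tad_gap):
                end = cand
                break
        tads.append((pos, end))
        pos = end + cfg.tad_gap
    if pos < genome.chrom_length:
        tads.append((pos, genome.chrom_length))
    return TADSet(tads=tads, chrom_length=genome.chrom_length)


def simulate_hic(genome: GenomeModel, cfg: HiCConfig):
    """Draw a symmetric integer contact matrix plus its planted TADs.

    Returns ``(ContactMatrix, TADSet, planted_pairs)`` where
    ``planted_pairs`` is the list of long-range (i, j) bin pairs that
    received ``planted_fold`` extra signal.
    """
    from .hic import ContactMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    n_full, rem = divmod(genome.chrom_length, cfg.bin_size)
    bins = [(k * cfg.bin_size, (k + 1) * cfg.bin_size) for k in range(n_full)]
    partial_bin = False
    if rem:
        bins.append((n_full * cfg.bin_size, genome.chrom_length))
        partial_bin = True
    n = len(bins)

    tadset = _plant_tads(genome, cfg, rng)

    mids = np.array([(s + e) // 2 for s, e in bins])
    tad_of = np.full(n, -1)
    for t, (s, e) in enumerate(tadset.tads):
        tad_of[(mids >= s) & (mids < e)] = t

    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mu = cfg.intensity / np.maximum(d, 1).astype(float) ** cfg.alpha
    same_tad = (tad_of[:, None] == tad_of[None, :]) & (tad_of[:, None] >= 0)
    mu = np.where(same_tad & (d > 0), mu * cfg.tad_enrichment, mu)

    planted_pairs: list[tuple[int, int]] = []
    if cfg.n_planted_bins is None or cfg.n_planted_bins >= 2:
        group_bins = sorted(
            {
                int(((g.start + g.end) // 2) // cfg.bin_size)
                for g in genome.genes
                if g.group == cfg.plant_on_group
            }
        )
        group_bins = [b for b in group_bins if b < n]
        if cfg.n_planted_bins is None:
            chosen_bins = group_bins
        else:
            take = min(cfg.n_planted_bins, len(group_bins))
            chosen = sorted(rng.choice(len(group_bins), size=take, replace=False))
            chosen_bins = [group_bins[c] for c in chosen]
        for a_i in range(len(chosen_bins)):
            for b_i in range(a_i + 1, len(chosen_bins)):
                i, j = chosen_bins[a_i], chosen_bins[b_i]
                if abs(i - j) < 2:
                    continue
                mu[i, j] *= cfg.planted_fold
                mu[j, i] *= cfg.planted_fold
                planted_pairs.append((i, j))

    upper = np.triu_indices(n)
    counts = np.zeros((n, n), dtype=np.int64)
    draws = rng.poisson(mu[upper])
    counts[upper] = draws
    counts = counts + np.triu(counts, 1).T

    matrix = ContactMatrix(
        chrom=genome.chrom_name, bins=bins, counts=counts, partial_last_bin=partial_bin
    )
    return matrix, tadset, planted_pairs


# ---------------------------------------------------------------------------
# PPI


@dataclass(frozen=True)
class PPIConfig:
    """Degree-biased random interaction network: essential genes draw
    ``degree_ratio`` times the non-essential mean degree."""

    mean_degree: float = 4.0
    degree_ratio: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree_ratio < 0:
            raise ConfigurationError("degree_ratio must be non-negative")
        if self.mean_degree <= 0:
            raise ConfigurationError("mean_degree must be positive")


def simulate_ppi(genome: GenomeModel, cfg: PPIConfig) -> list[tuple[str, str]]:
    """Undirected, deduplicated, self-loop-free edge list over gene ids."""
    genes = [g.gene_id for g in genome.genes]
    weights = [
        cfg.mean_degree * (cfg.degree_ratio if g.essential else 1.0)
        for g in genome.genes
    ]
    rng_seed = int(np.random.default_rng(cfg.seed).integers(0, 2**31 - 1))
    g = nx.expected_degree_graph(weights, seed=rng_seed, selfloops=False)
    edges = sorted(
        (genes[min(u, v)], genes[max(u, v)]) for u, v in g.edges() if u != v
    )
    return edges


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionConfig:
    """Stage-course read counts with stage-peaked co-expression modules.

    Eight modules peak at fixed stages spanning the course; essential
    genes join an early-embryonic module with probability
    ``essential_early_prob`` (the planted ground truth that essential
    genes act early in development)."""

    module_peaks: tuple[int, ...] = (1, 3, 5, 8, 11, 15, 17, 20)  # 0-based stage idx
    peak_width: float = 2.0
    baseline: float = 0.2
    depth: float = 200.0
    essential_early_prob: float = 0.85
    library_size: float = 5e6
    seed: int = 0


def simulate_expression(genome: GenomeModel, cfg: ExpressionConfig):
    """Returns ``(raw_counts, library_sizes, module_truth)``.

    ``raw_counts`` is a genes x 23 integer DataFrame of reads; library
    sizes vary ~20% around ``library_size``; ``module_truth`` maps gene id
    -> planted module index.
    """
    rng = np.random.default_rng(cfg.seed)
    n_stage = len(STAGE_NAMES)
    stages = np.arange(n_stage)
    early_modules = [m for m, p in enumerate(cfg.module_peaks) if p < 6]

    libs = cfg.library_size * rng.uniform(0.8, 1.2, size=n_stage)
    truth: dict[str, int] = {}
    rows = []
    for g in genome.genes:
        if g.essential and rng.random() < cfg.essential_early_prob:
            m = early_modules[int(rng.integers(len(early_modules)))]
        else:
            m = int(rng.integers(len(cfg.module_peaks)))
        truth[g.gene_id] = m
        peak = cfg.module_peaks[m]
        profile = cfg.baseline + np.exp(-((stages - peak) ** 2) / (2 * cfg.peak_width**2))
        lam = cfg.depth * profile * (g.coding_length / 1000.0) * (libs / cfg.library_size)
        rows.append(rng.poisson(lam))
    raw = pd.DataFrame(
        np.array(rows, dtype=np.int64),
        index=[g.gene_id for g in genome.genes],
        columns=list(STAGE_NAMES),
    )
    library_sizes = pd.Series(libs, index=list(STAGE_NAMES), name="library_size")
    return raw, library_sizes, truth
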