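# Methods

## The screening model

`lethalmap` analyzes whole-genome sequencing of mutant strains in which a
recessive lethal mutation is kept alive by a free chromosomal duplication
carrying the wild-type allele. Such a strain has three copies of every
balanced locus — two on the normal chromosomes (both mutant at the lethal
site) and one rescuing copy on the duplication — so reads supporting the
lethal allele are expected at a fraction of 2/3 of the pileup. A locus the
duplication does not cover is homozygous on two of two copies, expected
allele balance 1.0. Two engineered marker mutations, one balanced
(expectation 2/3) and one unbalanced (expectation 1.0), serve as a strain
identity check.

Candidate lethal SNVs are those whose observed allele balance lies in a
band around the 2/3 expectation, with adequate read support, after
removing variants the un-mutagenized starting strain already carried:

1. **Strain QC.** A strain is discarded if either marker mutation is
   absent or outside its acceptance window, or if genome-wide mean depth
   is strictly below 8X. Marker failures are reported before coverage
   failures; a strain at exactly 8.0X passes.
2. **Allele-balance band.** Keep SNVs with ratio in [0.40, 0.90],
   *inclusive* at both bounds. The band tolerates binomial sampling noise
   around 2/3 at ~23X while excluding homozygous (≈1.0) and most
   spurious low-fraction calls.
3. **Read support.** Keep SNVs with at least 8 alternate reads in total
   and at least one on each strand. We read the support rule as a total
   count with a both-strands presence requirement, not 8 per strand —
   8 per strand would demand 16 alternate reads, implausible at 23X mean
   depth with a 2/3 allele fraction. Both the threshold and the
   both-strands requirement are configurable.
4. **Background subtraction.** Remove SNVs matching the starting-strain
   variant set on (chrom, pos, alt). Matching is allele-aware: a
   different alternate allele at a known background position is kept
   (with a logged warning).

The three filters are pure set operations: idempotent and commuting, a
property the test suite checks.

**Marker acceptance windows.** Only expectations, not windows, follow
from the copy-number model, so the package uses the candidate band
[0.40, 0.90] for the balanced marker and ratio ≥ 0.90 for the
unbalanced one.

**Evidence integration.** Surviving SNVs map to gene models; each
candidate is screened against the genetic-mapping zone assigned to its
strain's lethal (flagged, never silently dropped), and graded with a
documented tier rule: *high* = in-zone + independent lethality support
(RNAi phenotype or known lethal allele) + no homozygous-viable disruptive
allele in a large mutant catalog; *supported* = in-zone + catalog-clean;
*candidate* otherwise. The source material describes these as qualitative
"lines of evidence"; the tier table is this package's formalization and is
monotone in every positive flag. Consequence annotation translates coding
SNVs through the standard code (stop gain = nonsense, reported as e.g.
"Q->X") and classifies intronic positions within ±2 bp of an exon
junction as splice donor/acceptor in transcription orientation (the
canonical GT/AG dinucleotides motivate the 2-bp window). Candidates
sharing a gene merge into one essential-gene call; allele identity is
(position, alternate allele); strains hitting more than one gene are
reported as multi-hit, mirroring ambiguous assignments in the source
catalog, and left unresolved.

## Downstream gene-essentiality genomics

**Hi-C locus clustering.** Contacts are binned at 50 kb, balanced by
iterative correction (ICE: repeated division by row-sum factors anchored
at their geometric mean, so the matrix scale is preserved; all-zero bins
masked; convergence = all unmasked row sums within `tol` of their mean,
honestly flagged otherwise). Pair significance follows the Fit-Hi-C
scheme: the chromosome's contacts are treated as a multinomial draw over
locus pairs, a pair's expected probability comes from an empirical
distance-decay curve, and the p-value is the upper binomial tail at the
observed raw count. Pairs need ≥ 15 raw contacts and separation ≥ 2 bins
to be eligible; calls use raw P < 0.01 with no multiple-testing
correction (matching the procedure this reimplements, which states a raw
P threshold).

*Distance-decay estimation.* The expectation is computed per unique bin
separation, pooling only separations with fewer than `min_occupancy`
(default 30) pairs into equal-occupancy strata at the sparse far tail.
Equal-width occupancy strata that ignore separation boundaries pool
near-diagonal separations whose expectations differ by 30–50%, which
inflates the upper tail and breaks the test's calibration; per-separation
means are the discrete analog of the spline smoothing used by the
original significance method.

*ICE biases and the expectation.* By default the expectation is built
from raw counts. On maps whose bins are equally visible (including all
maps this generator produces), ICE biases are finite-chromosome artifacts
— edge bins lose close-range partners, so balancing assigns them
systematically low factors — and rescaling the expectation by
`bias_i · bias_j` spreads per-pair z-scores several-fold without any real
signal. `bias_rescale=True` restores the rescaled expectation for data
whose biases reflect genuine visibility (mappability, restriction-site
density).

*Grouping.* Every locus with ≥ 2 significant partners seeds a group of
itself plus its partners; overlapping groups are unioned until disjoint
(`merge=False` keeps per-seed neighborhoods). A gene belongs to a group
when its body overlaps a member locus; its contact (cluster) frequency is
the number of distinct *other* genes sharing a group with it — partner
genes, not locus memberships, which matches the "interaction partners"
reading of the procedure.

**TAD boundaries.** Boundaries are the regions between consecutive
domains, optionally widened by a flank (default 0 bp — the source never
states a width). Genes classify as boundary (any overlap of the gene
body; a TSS-point mode is provided since boundary studies often use
TSSs), interior, or outside; group-wise boundary occupancy is compared
with a two-sided Fisher's exact test on the boundary/interior 2×2 table,
outside genes excluded and counted.

**Group comparisons.** Following the source's reporting, every
location comparison runs Brown–Forsythe (median-centered Levene) for
variance homogeneity alongside a two-sided Wilcoxon rank-sum /
Mann-Whitney U p-value (these are the same test under two names; which
"branch" the Levene outcome selected in the source is unknowable, so both
quantities are always reported, plus Welch's t as a diagnostic). The
rank-sum test uses the exact permutation null for combined n ≤ 20
without ties, otherwise the normal approximation with tie-corrected
variance and continuity correction.

**Overrepresentation.** Per annotation term, a two-sided Fisher's exact
test contrasts the study set with the rest of the population; fold
enrichment is study frequency over population frequency; Bonferroni
multiplies by the number of tested terms (terms without population hits
are skipped and logged).

**Expression.** Values are reads per coding-length-kb per million mapped
reads over a fixed 23-stage course (18 embryo time points, L1–L4, young
adult), then mean-centered per gene. Co-expression modules come from
average-linkage hierarchical clustering on 1 − Pearson distance with a
fixed module count (default 8); this deliberately replaces weighted
co-expression network analysis (soft thresholding, topological overlap,
dynamic tree cut), which the source used only to produce module labels.
Constant-expression genes form a separate "flat" module. A module's peak
phase is the phase of its mean profile's argmax; embryo stages split into
thirds (early 1–6, mid 7–12, late 13–18) because the source's phase
vocabulary is not numerically defined, and post-embryonic stages
(L1–young adult) form the larval bucket.

**PPI connectivity.** Degree per gene after collapsing reversed and
repeated edges and dropping self-loops; genes absent from the network
score 0 over a configurable gene universe (default: the gene models).

## The synthetic-data generator

The generator plants ground truth for every stage on a single ~7.3 Mb
chromosome whose first 5.4 Mb are covered by the balancing duplication.
Defaults are the study conditions the pipeline is specified against:

| quantity | default | rationale |
|---|---|---|
| strains / marker failures / low coverage | 130 / 23 / 4 | the cohort composition of the screen emulated |
| mean depth (passing strains) | 23X | reported average |
| lethal allele balance | Binomial(depth, 2/3), strand split Bernoulli(0.5) | copy-number model |
| background variants | 60 shared loci at ratios {0.5, 1.0} | heterozygous/homozygous starting-strain variants; makes subtraction testable |
| genes / groups G1–G4 | 400 / 8–40–80–272 | desk-scale; preserves the catalog's skew toward non-essential genes |
| Hi-C | 50-kb bins, counts Poisson with (separation)^-1 decay, intensity 4500 | every eligible pair comfortably above the 15-count floor |
| planted domains | ~250 kb, ×3 within-domain, 10 kb gaps nudged off essential genes | essential genes live inside domains (boundary-depletion ground truth) |
| planted contact clique | ×10 over all pairs of G2-bearing bins | the gene-cluster ground truth must cover the gene set it claims to enrich |
| PPI | expected-degree graph, essential:non-essential mean degree 3:1, base 4 | hub direction |
| expression | 8 Gaussian stage-peaked modules, essential genes early-embryonic w.p. 0.85 | early-development direction |

Marker read counts of strains designated to pass QC are rejection-sampled
into the marker acceptance windows: the planted QC verdict is ground
truth, so the generator guarantees it realizes (unconditioned sampling
would misclassify ~2–3% of strains at 23X and make the planted cohort
accounting stochastic). Lethal and background variants are *not*
conditioned — their filter survival is exactly the binomial band
probability, which the tests compute by direct pmf summation
(≈ 0.987 at 23X, hence the ≥ 95% recovery check).

Two named Hi-C scenarios fix the study conditions for calibration and
recovery: `hic_null_config` (pure decay; every call is a false positive)
and `hic_cluster_scenario` (the G2 clique on a domain-free background).
The clique-on-null design is deliberate: at 146 bins, domain-scale
significance plus the test's nominal 1% false-positive rate percolates
union-merged groups into one giant component, which erases group
membership as a signal — an instructive limitation of neighborhood
union-merging on dense maps, and the reason the default domain-enriched
map is not used for the clustering-direction check.

**What the generator does not emulate:** alignment and base-calling
error, indels and structural variants, mappability/visibility bias in
Hi-C (hence the raw-count expectation default), correlated noise between
strains, library-preparation batch effects, and the real genome's gene
density and length distributions. Passing tests demonstrate the
*procedures* are implemented correctly and recover planted structure;
they do not certify performance on real sequencing data.

## Numerical choices

- ICE: tolerance 1e-5 on relative row-sum deviation, max 200 iterations,
  geometric-mean anchoring; convergence reported, never assumed.
- Binomial tails via `scipy.stats.binom.sf` (survival function at k−1);
  a zero expectation with positive count is flagged and assigned the
  smallest positive float rather than 0.
- Exact vs asymptotic rank-sum switch at combined n = 20, exact only
  without ties.
- Degenerate Levene inputs (zero spread of the centered deviations)
  return p = 1 (identical spreads) or 0 (different constant spreads)
  instead of NaN.
- Coordinates: variants 1-based (VCF), intervals 0-based half-open
  (BED); conversions confined to `lethalmap.io`.
- Seeds are mandatory; every stage derives independent child seeds from
  one root via `numpy.random.SeedSequence`.

## Problem sizes

Default runs use 400 genes, 130 strains (~6.4k variant records), a
146-bin contact matrix (~10.4k eligible pairs), ~1.4k PPI edges and a
400 × 23 expression matrix; the full pipeline completes in under a
second and the whole test suite in well under a minute. These sizes were
chosen so every planted effect is detectable with wide margins while
remaining instant to iterate on.

## Known limitations

- Raw-P significance calling (no FDR) follows the reimplemented
  procedure; on larger maps the nominal 1% false-positive rate produces
  many spurious pairs, and union-merged groups can percolate (see above).
- The tier rule is a formalization of qualitative evidence language;
  alternative rule tables are configuration, not code.
- The published catalog's "35 of 44 conserved in all examined organisms"
  does not match its own table (36 rows carry all four clades); the
  summary reports the computed 36 and documents the discrepancy.
- Module labels from hierarchical clustering are not expected to
  reproduce WGCNA's labels on real data; only stage-peak structure is
  asserted.
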