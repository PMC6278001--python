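"""Hi-C contact binning, ICE normalization, interaction significance and
locus grouping.

Significance follows the Fit-Hi-C scheme: contacts are modelled as a
multinomial draw of the chromosome's total contacts over locus pairs,
with each pair's success probability set by an empirical distance-decay
expectation (per-separation strata, optionally re-scaled by the pair's
ICE biases when bin visibility differences are real). A pair with at
least ``min_count`` raw contacts is significant when its upper-tail
binomial p-value is below ``alpha``; no multiple-testing correction is
applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .models import ConfigurationError, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "ICEResult",
    "SignificantInteraction",
    "LocusGroup",
    "ExpectedModel",
    "bin_contacts",
    "ice_normalize",
    "expected_by_distance",
    "call_significant",
    "group_loci",
    "gene_contact_frequency",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts over one chromosome.

    ``bins`` are 0-based half-open intervals of uniform width (the last
    bin may be shorter; ``partial_last_bin`` flags it)."""

    chrom: str
    bins: list[tuple[int, int]]
    counts: np.ndarray
    partial_last_bin: bool = False

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ConfigurationError("counts shape does not match bins")
        if (self.counts < 0).any():
            raise ConfigurationError("negative contact count")
        if not np.array_equal(self.counts, self.counts.T):
            raise ConfigurationError("contact matrix is not symmetric")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def total_contacts(self) -> int:
        """Sum over the strict upper triangle (inter-locus contacts)."""
        return int(np.triu(self.counts, 1).sum())


def bin_contacts(
    pairs: Iterable[tuple[int, int]],
    chrom: str,
    chrom_length: int,
    bin_size: int,
) -> ContactMatrix:
    """Assign bp-level contact pairs to bins; symmetry by mirroring.

    A trailing partial bin is retained and flagged. Contacts beyond the
    chromosome end raise a coordinate error.
    """
    n_full, rem = divmod(chrom_length, bin_size)
    bins = [(k * bin_size, (k + 1) * bin_size) for k in range(n_full)]
    partial = False
    if rem:
        bins.append((n_full * bin_size, chrom_length))
        partial = True
        logger.warning(
            "bin size %d does not divide %d; last bin is %d bp",
            bin_size, chrom_length, rem,
        )
    n = len(bins)
    counts = np.zeros((n, n), dtype=np.int64)
    for a, b in pairs:
        if not (0 <= a < chrom_length and 0 <= b < chrom_length):
            raise ConfigurationError(f"contact ({a},{b}) outside chromosome")
        i, j = a // bin_size, b // bin_size
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    return ContactMatrix(chrom=chrom, bins=bins, counts=counts, partial_last_bin=partial)


@dataclass
class ICEResult:
    bias: np.ndarray          # positive per-bin factors; masked bins = NaN
    normalized: np.ndarray    # counts[i,j] / (bias[i]*bias[j])
    mask: np.ndarray          # True for bins kept
    n_iter: int
    converged: bool


def ice_normalize(
    m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ICEResult:
    """Iterative correction (matrix balancing) of a contact matrix.

    Repeatedly divides by current row-sum factors, anchored to the
    geometric mean so the overall scale of the matrix is untouched.
    All-zero bins are masked and excluded from balancing. Convergence is
    reached when every unmasked row sum is within ``tol`` (relative) of
    their common mean.
    """
    counts = m.counts.astype(float)
    mask = counts.sum(axis=1) > 0
    if not mask.any():
        raise ConfigurationError("contact matrix has no non-zero bin")
    w = counts[np.ix_(mask, mask)].copy()
    bias = np.ones(w.shape[0])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s = w.sum(axis=1)
        dev = np.abs(s / s.mean() - 1).max()
        if dev < tol:
            converged = True
            break
        delta = s / np.exp(np.log(s).mean())  # geometric-mean anchor
        w /= np.outer(delta, delta)
        bias *= delta
    full_bias = np.full(m.n_bins, np.nan)
    full_bias[mask] = bias
    normalized = np.full_like(counts, np.nan)
    normalized[np.ix_(mask, mask)] = w
    return ICEResult(bias=full_bias, normalized=normalized, mask=mask, n_iter=n_iter, converged=converged)


@dataclass
class ExpectedModel:
    """Per-pair expected contact probabilities under distance decay.

    Arrays are parallel over eligible pairs (i < j, separation >=
    ``min_separation`` bins, both bins unmasked)."""

    pair_i: np.ndarray
    pair_j: np.ndarray
    prob: np.ndarray           # sums to 1 over eligible pairs
    total_contacts: int        # raw contacts over eligible pairs
    min_separation: int


def expected_by_distance(
    m: ContactMatrix,
    ice: ICEResult,
    min_occupancy: int = 30,
    min_separation: int = 2,
    bias_rescale: bool = False,
) -> ExpectedModel:
    """Empirical distance-decay expectation on distance strata.

    Each unique bin separation forms its own stratum (the discrete analog
    of a smoothed distance-decay curve — pooling separations with very
    different decay expectations would bias the near-diagonal tail of the
    test); separations with fewer than ``min_occupancy`` pairs are pooled
    with consecutive neighbors into equal-occupancy strata.

    By default a pair's expected probability is its stratum's mean raw
    count, renormalized over eligible pairs. With ``bias_rescale`` the
    stratum mean is taken on the ICE-normalized matrix and scaled back by
    the pair's biases — appropriate when bin visibility differences are
    real; on uniform-visibility data the ICE biases are finite-size
    artifacts of the decay profile and rescaling by them distorts the
    per-pair expectation.
    """
    n = m.n_bins
    ii, jj = np.triu_indices(n, k=min_separation)
    keep = ice.mask[ii] & ice.mask[jj]
    ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        raise ConfigurationError("no eligible locus pair")
    dist = jj - ii
    norm = ice.normalized[ii, jj] if bias_rescale else m.counts[ii, jj].astype(float)

    strata: list[np.ndarray] = []
    pending: list[np.ndarray] = []
    pending_n = 0
    for d in np.unique(dist):
        idx = np.nonzero(dist == d)[0]
        pending.append(idx)
        pending_n += idx.size
        if pending_n >= min_occupancy:
            strata.append(np.concatenate(pending))
            pending, pending_n = [], 0
    if pending:  # sparse far tail: fold into the last stratum
        tail = np.concatenate(pending)
        if strata:
            strata[-1] = np.concatenate([strata[-1], tail])
        else:
            strata.append(tail)
    mean_norm = np.empty(ii.size)
    for idx in strata:
        mean_norm[idx] = norm[idx].mean()

    expected = mean_norm * ice.bias[ii] * ice.bias[jj] if bias_rescale else mean_norm
    total = expected.sum()
    if total <= 0:
        raise ConfigurationError("degenerate expectation (all-zero strata)")
    prob = expected / total
    raw_total = int(m.counts[ii, jj].sum())
    return ExpectedModel(
        pair_i=ii, pair_j=jj, prob=prob,
        total_contacts=raw_total, min_separation=min_separation,
    )


@dataclass(frozen=True)
class SignificantInteraction:
    locus_i: int
    locus_j: int
    raw_count: int
    expected_prob: float
    p_value: float


def call_significant(
    m: ContactMatrix,
    expected: ExpectedModel,
    min_count: int = 15,
    alpha: float = 0.01,
) -> list[SignificantInteraction]:
    """Upper-tail binomial test of each eligible pair's raw count.

    ``p = P[Binomial(N, p_ij) >= k]`` with N the total raw contacts over
    eligible pairs. Pairs with fewer than ``min_count`` raw contacts are
    never called. A zero expectation with a positive count is flagged and
    assigned the smallest positive float.
    """
    k = m.counts[expected.pair_i, expected.pair_j]
    eligible = k >= min_count
    pvals = np.ones(k.shape)
    pos = eligible & (expected.prob > 0)
    pvals[pos] = sps.binom.sf(k[pos] - 1, expected.total_contacts, expected.prob[pos])
    degenerate = eligible & (expected.prob == 0) & (k > 0)
    if degenerate.any():
        logger.warning("%d pairs with zero expectation but positive counts", degenerate.sum())
        pvals[degenerate] = np.finfo(float).tiny
    out = []
    for idx in np.nonzero(eligible & (pvals < alpha))[0]:
        out.append(
            SignificantInteraction(
                locus_i=int(expected.pair_i[idx]),
                locus_j=int(expected.pair_j[idx]),
                raw_count=int(k[idx]),
                expected_prob=float(expected.prob[idx]),
                p_value=float(pvals[idx]),
            )
        )
    return out


@dataclass
class LocusGroup:
    member_loci: frozenset[int]
    member_genes: frozenset[str] = field(default_factory=frozenset)


def group_loci(
    sig: Sequence[SignificantInteraction],
    min_partners: int = 2,
    merge: bool = True,
) -> list[LocusGroup]:
    """Group loci around hubs of significant interaction.

    Every locus with at least ``min_partners`` significant partners seeds
    a group of itself plus all its partners. With ``merge`` (default),
    overlapping groups are unioned until disjoint; with ``merge=False``
    each seed's closed neighborhood is returned as-is.
    """
    nbrs: dict[int, set[int]] = {}
    for s in sig:
        nbrs.setdefault(s.locus_i, set()).add(s.locus_j)
        nbrs.setdefault(s.locus_j, set()).add(s.locus_i)
    seeds = [u for u, vs in nbrs.items() if len(vs) >= min_partners]
    groups = [frozenset({u} | nbrs[u]) for u in sorted(seeds)]
    if not merge:
        return [LocusGroup(g) for g in groups]
    merged: list[set[int]] = []
    for g in groups:
        g = set(g)
        absorbed = []
        for existing in merged:
            if existing & g:
                g |= existing
                absorbed.append(existing)
        for a in absorbed:
            merged.remove(a)
        merged.append(g)
    merged.sort(key=min)
    return [LocusGroup(frozenset(g)) for g in merged]


def gene_contact_frequency(
    groups: Sequence[LocusGroup],
    genes: Sequence[GeneModel],
    bins: Sequence[tuple[int, int]],
) -> dict[str, int]:
    """Count each gene's distinct interaction partners via locus groups.

    A gene belongs to a group when its body overlaps any member locus;
    its frequency is the number of *other* distinct genes sharing at
    least one group with it. Genes in no group score 0.
    """
    partners: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for grp in groups:
        members = [
            g.gene_id
            for g in genes
            if any(g.overlaps(*bins[locus]) for locus in grp.member_loci)
        ]
        grp.member_genes = frozenset(members)
        for gid in members:
            partners[gid].update(m for m in members if m != gid)
    return {gid: len(p) for gid, p in partners.items()}
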