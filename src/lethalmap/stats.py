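"""Shared statistical kernel.

Group-location comparisons follow the two-step recipe used throughout
the downstream analyses: a Brown-Forsythe (median-centered Levene) test
of variance homogeneity is reported alongside a two-sided Wilcoxon
rank-sum / Mann-Whitney U p-value for the location difference (the two
names denote the same test; Welch's t is reported as a diagnostic).
Overrepresentation of annotation terms in a study set against a
population uses a two-sided Fisher's exact test per term with Bonferroni
correction across terms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "EnrichmentResult",
    "levene_test",
    "ranksum_test",
    "compare_groups",
    "fisher_exact_2x2",
    "overrepresentation",
]


def levene_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Brown-Forsythe test of equal variances (one-way ANOVA F on
    median-centered absolute deviations). Returns the p-value; degenerate
    inputs with zero between- and within-spread (e.g. identical constant
    groups) return p = 1."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    if np.ptp(np.concatenate([za, zb])) == 0:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = sps.levene(a, b, center="median")
    if not np.isfinite(p):  # zero within-group spread: any difference is extreme
        return 0.0 if np.median(za) != np.median(zb) else 1.0
    return float(p)


def ranksum_test(
    a: Sequence[float], b: Sequence[float], exact_threshold: int = 20
) -> float:
    """Two-sided Mann-Whitney U / Wilcoxon rank-sum p-value.

    The exact permutation distribution is used when the combined sample
    size is at most ``exact_threshold`` and there are no ties; otherwise
    the normal approximation with tie-corrected variance and continuity
    correction.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size + b.size <= exact_threshold
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    levene_p: float
    ranksum_p: float
    welch_p: float  # diagnostic only


def compare_groups(
    label_a: str,
    values_a: Sequence[float],
    label_b: str,
    values_b: Sequence[float],
) -> GroupComparison:
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    welch = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        levene_p=levene_test(a, b),
        ranksum_p=ranksum_test(a, b),
        welch_p=float(welch.pvalue),
    )


def fisher_exact_2x2(
    table: Sequence[Sequence[int]],
) -> tuple[float, float]:
    """Two-sided Fisher's exact test (sum of hypergeometric probabilities
    of tables at least as extreme as the observed one, at fixed margins).
    Returns (odds_ratio, p)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    study_hits: int
    study_n: int
    pop_hits: int
    pop_n: int
    fold: float
    p_raw: float
    p_bonferroni: float
    direction: str  # over | under


def overrepresentation(
    study: set[str],
    population: set[str],
    annotation: Mapping[str, set[str]],
) -> list[EnrichmentResult]:
    """Per-term overrepresentation of a study set within a population.

    For each term the 2x2 table contrasts the study set with the rest of
    the population; fold enrichment is the ratio of term frequency in the
    study to its frequency in the whole population, direction is over or
    under as fold exceeds or falls below 1. Bonferroni multiplies raw
    p-values by the number of *tested* terms (terms without any
    population hit are skipped and logged).
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    study_n, pop_n = len(study), len(population)
    tested = []
    for term, members in annotation.items():
        pop_hits = len(members & population)
        if pop_hits == 0:
            logger.info("term %s has no population hits; skipped", term)
            continue
        tested.append((term, members, pop_hits))
    n_terms = len(tested)
    out = []
    for term, members, pop_hits in tested:
        sh = len(members & study)
        table = [
            [sh, study_n - sh],
            [pop_hits - sh, (pop_n - study_n) - (pop_hits - sh)],
        ]
        _, p = fisher_exact_2x2(table)
        fold = (sh / study_n) / (pop_hits / pop_n) if study_n else float("nan")
        out.append(
            EnrichmentResult(
                term=term,
                study_hits=sh,
                study_n=study_n,
                pop_hits=pop_hits,
                pop_n=pop_n,
                fold=fold,
                p_raw=p,
                p_bonferroni=min(1.0, p * n_terms),
                direction="over" if fold >= 1 else "under",
            )
        )
    return out
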