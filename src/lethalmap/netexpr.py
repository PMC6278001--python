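"""Protein-interaction degree and developmental-expression profiling.

Expression values are normalized to reads per coding-length-kb per
million mapped reads, then mean-centered per gene across the 23-stage
course (18 embryo time points, L1-L4, young adult). Co-expression
modules come from average-linkage hierarchical clustering on
1 - Pearson correlation — a deliberately simple stand-in for weighted
co-expression network analysis that reproduces stage-peaked module
labels on planted data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .models import ConfigurationError
from .simulate import STAGE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionModule",
    "ppi_degree",
    "normalize_expression",
    "center_rows",
    "cluster_modules",
    "stage_phase",
]


def ppi_degree(
    edges: Iterable[tuple[str, str]],
    universe: Optional[Iterable[str]] = None,
) -> dict[str, int]:
    """Interaction count per gene from an undirected edge list.

    Reversed and repeated duplicates collapse to one edge; self-loops are
    dropped with a warning. Genes in ``universe`` absent from all edges
    score 0.
    """
    unique: set[frozenset[str]] = set()
    n_loops = 0
    for u, v in edges:
        if u == v:
            n_loops += 1
            continue
        unique.add(frozenset((u, v)))
    if n_loops:
        logger.warning("dropped %d self-loop(s)", n_loops)
    degree: dict[str, int] = {g: 0 for g in universe} if universe else {}
    for e in unique:
        for g in e:
            degree[g] = degree.get(g, 0) + 1
    return degree


def normalize_expression(
    raw: pd.DataFrame,
    coding_length: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Reads per coding-length-kb per million mapped reads.

    ``raw`` is genes x stages counts; ``coding_length`` in bp per gene;
    ``library_sizes`` in reads per stage column.
    """
    cl = pd.Series(coding_length).reindex(raw.index)
    if cl.isna().any():
        missing = list(cl.index[cl.isna()])[:3]
        raise ConfigurationError(f"missing coding length for {missing}")
    if (cl <= 0).any():
        bad = list(cl.index[cl <= 0])[:3]
        raise ConfigurationError(f"non-positive coding length for {bad}")
    libs = pd.Series(library_sizes).reindex(raw.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise ConfigurationError("invalid library sizes")
    return raw.div(cl / 1_000.0, axis=0).div(libs / 1_000_000.0, axis=1)


def center_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across stages (rows end up mean-zero)."""
    return m.sub(m.mean(axis=1), axis=0)


#: Phase buckets over the 23-stage course: embryo stages split in thirds,
#: then larval (young adult folded into the post-embryonic bucket).
_PHASES = (
    ("early-embryonic", range(0, 6)),
    ("mid-embryonic", range(6, 12)),
    ("late-embryonic", range(12, 18)),
    ("larval", range(18, len(STAGE_NAMES))),
)


def stage_phase(stage_index: int) -> str:
    for name, rng in _PHASES:
        if stage_index in rng:
            return name
    raise ValueError(f"stage index {stage_index} out of range")


@dataclass
class ExpressionModule:
    module_id: str
    members: tuple[str, ...]
    peak_stage: int
    peak_phase: str


def cluster_modules(centered: pd.DataFrame, k: int) -> list[ExpressionModule]:
    """Average-linkage hierarchical clustering on 1 - Pearson distance.

    Constant rows (zero variance, undefined correlation) are collected
    into their own ``flat`` module. Each module's peak phase is the phase
    of the argmax of its mean profile. Modules partition the input genes.
    """
    if k < 1 or k > centered.shape[0]:
        raise ConfigurationError(f"k={k} outside 1..n_genes")
    variable = centered.std(axis=1) > 0
    flat_genes = tuple(centered.index[~variable])
    x = centered.loc[variable]
    modules: list[ExpressionModule] = []
    if x.shape[0] == 1:
        labels = np.array([1])
    elif x.shape[0] > 1:
        z = hierarchy.linkage(x.to_numpy(), method="average", metric="correlation")
        labels = hierarchy.fcluster(z, t=min(k, x.shape[0]), criterion="maxclust")
    else:
        labels = np.array([], dtype=int)
    for lab in sorted(set(labels)):
        members = tuple(x.index[labels == lab])
        profile = x.loc[list(members)].mean(axis=0).to_numpy()
        peak = int(profile.argmax())
        modules.append(
            ExpressionModule(
                module_id=f"module_{lab:02d}",
                members=members,
                peak_stage=peak,
                peak_phase=stage_phase(peak),
            )
        )
    if flat_genes:
        modules.append(
            ExpressionModule(
                module_id="flat", members=flat_genes, peak_stage=-1, peak_phase="mixed"
            )
        )
    return modules
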