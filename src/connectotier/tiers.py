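"""Degree-quartile tier decomposition of a connectome.

Each subject's binarised connectome is split into four tiers by quartiles
of its own maximum degree k_max: Tier 1 holds all nodes with degree
greater than 0.75 k_max (the hub stratum), Tier 2 those with degree
greater than 0.5 k_max and up to 0.75 k_max, Tier 3 greater than
0.25 k_max and up to 0.5 k_max, and Tier 4 the remainder (including any
isolated nodes).  Boundaries are recomputed per subject, so a tier is a
subject-specific stratum of the degree hierarchy, not a fixed region set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph_core import BinaryGraph, degree_sequence
from .metrics import average_clustering, hierarchical_complexity

__all__ = [
    "TierAssignment",
    "TierMetrics",
    "assign_tiers",
    "tier_metrics",
    "tier_frequency",
    "tier_placement_correlation",
    "TIERS",
]

log = logging.getLogger(__name__)

TIERS = (1, 2, 3, 4)


@dataclass(frozen=True)
class TierAssignment:
    """Node -> tier map for one subject (tiers partition the node set)."""

    tier_of: np.ndarray  # int array of length n, values in {1,2,3,4}
    k_max: int
    boundaries: tuple[float, float, float]  # (0.75, 0.5, 0.25) * k_max
    labels: tuple[str, ...]

    def nodes_in(self, tier: int) -> np.ndarray:
        return np.flatnonzero(self.tier_of == tier)


def assign_tiers(g: BinaryGraph) -> TierAssignment:
    """Quartile-of-maximum-degree tier assignment.

    Tier t holds nodes with (1 - 0.25 t) k_max < k <= (1.25 - 0.25 t) k_max;
    upper bounds inclusive, lower bounds exclusive.  Isolated nodes fall in
    Tier 4 (k = 0 <= 0.25 k_max) and trigger a warning.
    """
    k = degree_sequence(g)
    k_max = int(k.max())
    if k_max < 1:
        raise ValueError("cannot assign tiers on an empty graph")
    cuts = (0.75 * k_max, 0.5 * k_max, 0.25 * k_max)
    tier = np.full(g.n, 4, dtype=int)
    tier[k > cuts[2]] = 3
    tier[k > cuts[1]] = 2
    tier[k > cuts[0]] = 1
    if (k == 0).any():
        log.warning("%d isolated node(s) assigned to Tier 4", int((k == 0).sum()))
    return TierAssignment(tier_of=tier, k_max=k_max, boundaries=cuts, labels=g.labels)


@dataclass(frozen=True)
class TierMetrics:
    """Per-tier metric panel; empty tiers carry NaN, never zero."""

    average_degree: dict[int, float]
    clustering: dict[int, float]
    complexity: dict[int, float]
    node_count: dict[int, int]


def tier_metrics(g: BinaryGraph, assignment: TierAssignment) -> TierMetrics:
    """Mean degree, average local clustering and within-tier hierarchical
    complexity for each tier.

    Clustering and complexity are evaluated on the tier's nodes using
    full-graph degrees and neighbourhoods (tiers are node groupings, not
    subgraphs)."""
    if assignment.tier_of.shape[0] != g.n:
        raise ValueError("tier assignment does not match graph size")
    k = degree_sequence(g)
    avg_k: dict[int, float] = {}
    clust: dict[int, float] = {}
    comp: dict[int, float] = {}
    count: dict[int, int] = {}
    for t in TIERS:
        nodes = assignment.nodes_in(t)
        count[t] = int(nodes.size)
        if nodes.size == 0:
            avg_k[t] = clust[t] = comp[t] = float("nan")
            continue
        avg_k[t] = float(k[nodes].mean())
        clust[t] = average_clustering(g, nodes)
        comp[t] = hierarchical_complexity(g, nodes)
    return TierMetrics(
        average_degree=avg_k, clustering=clust, complexity=comp, node_count=count
    )


def tier_frequency(
    assignments: Sequence[TierAssignment], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """ROI x tier matrix counting how often each region lands in each tier.

    Rows sum to the cohort size.  All assignments must share one label set.
    """
    if not assignments:
        raise ValueError("no assignments given")
    ref = tuple(labels) if labels is not None else assignments[0].labels
    counts = np.zeros((len(ref), len(TIERS)), dtype=int)
    for a in assignments:
        if a.labels != ref:
            raise ValueError("inconsistent ROI labels across assignments")
        for col, t in enumerate(TIERS):
            counts[a.tier_of == t, col] += 1
    return pd.DataFrame(counts, index=list(ref), columns=[f"tier{t}" for t in TIERS])


def tier_placement_correlation(a: pd.DataFrame, b: pd.DataFrame) -> dict[int, float]:
    """Pearson r, per tier, between two cohorts' per-ROI placement counts.

    NaN where either count vector is constant (correlation undefined).
    """
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("tier frequency tables must share ROI labels and tiers")
    out: dict[int, float] = {}
    for t in TIERS:
        x = a[f"tier{t}"].to_numpy(dtype=float)
        y = b[f"tier{t}"].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[t] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[t] = float(sps.pearsonr(x, y).statistic)
    return out
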