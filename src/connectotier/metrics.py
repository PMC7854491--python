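"""Global and node-subset network metrics.

Three families of metrics characterise a binarised connectome:

* clustering -- the average local clustering coefficient, a measure of
  homophily (the tendency of a node's neighbours to link to each other);
* degree variance -- heterogeneity of the degree distribution, reported
  normalised by the maximum variance achievable at the same node and link
  counts, so it lies in [0, 1] (0 for regular graphs, 1 for maximally
  heterogeneous ones such as stars at their own (n, m));
* hierarchical complexity R -- topological diversity across the degree
  hierarchy: nodes of equal degree are compared through their sorted
  neighbour-degree sequences, and R averages the positional sample
  variance of those sequences over all degrees shared by at least two
  nodes.  R = 0 exactly when same-degree nodes have identical connectivity
  profiles.

The maximum degree variance at fixed (n, m) is attained by one of two
extremal families: the quasi-complete graph (a clique built edge by edge)
or the quasi-star (hubs saturated one by one); the quasi-star on m links
is the complement of the quasi-complete graph on n(n-1)/2 - m links, and
complementation leaves the degree variance unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph_core import BinaryGraph, ConnectomeMatrix, degree_sequence
from .graph_core import mean_weight as _mean_weight
from .graph_core import network_density, threshold_to_density

__all__ = [
    "local_clustering",
    "average_clustering",
    "degree_variance",
    "max_degree_variance",
    "normalised_degree_variance",
    "hierarchical_complexity",
    "GlobalMetrics",
    "global_metrics",
]


def _triangle_counts(g: BinaryGraph) -> np.ndarray:
    a = g.adjacency.astype(float)
    return np.diag(a @ a @ a) / 2.0


def local_clustering(g: BinaryGraph, i: int) -> float:
    """C_i = 2 t_i / (k_i (k_i - 1)); zero when the node has degree < 2."""
    n = g.n
    if not 0 <= i < n:
        raise IndexError(f"node index {i} out of range for n={n}")
    k = int(g.adjacency[i].sum())
    if k < 2:
        return 0.0
    nbrs = np.flatnonzero(g.adjacency[i])
    t = g.adjacency[np.ix_(nbrs, nbrs)].sum() / 2.0
    return float(2.0 * t / (k * (k - 1)))


def average_clustering(g: BinaryGraph, nodes: Sequence[int] | None = None) -> float:
    """Unweighted mean of the local clustering coefficient over ``nodes``.

    Defaults to all nodes; this is the global clustering coefficient used
    throughout (the transitivity ratio is deliberately not used, so the
    global and per-tier quantities are the same statistic on different
    node sets).
    """
    k = degree_sequence(g).astype(float)
    t = _triangle_counts(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * t / (k * (k - 1.0)), 0.0)
    if nodes is None:
        return float(c.mean())
    idx = np.asarray(nodes, dtype=int)
    if idx.size == 0:
        raise ValueError("empty node subset")
    return float(c[idx].mean())


def _int_population_variance(k: np.ndarray) -> float:
    """Population variance of integers via exact integer sums.

    (n sum k^2 - (sum k)^2) / n^2 keeps the numerator exact, so equal
    multisets give bit-identical variances regardless of element order.
    """
    k = np.asarray(k, dtype=np.int64)
    n = k.size
    return float(n * int((k * k).sum()) - int(k.sum()) ** 2) / (n * n)


def degree_variance(g: BinaryGraph) -> float:
    """Population variance of the degree sequence, (1/n) sum (k_i - kbar)^2."""
    k = degree_sequence(g)
    if k.size < 2:
        raise ValueError("degree variance needs n >= 2")
    return _int_population_variance(k)


def _quasi_complete_degrees(n: int, m: int) -> np.ndarray:
    """Degree sequence of the quasi-complete graph with n nodes, m links.

    A clique on b nodes plus one extra node attached to r = m - b(b-1)/2
    clique members (0 <= r < b).
    """
    b = 1
    while (b + 1) * b // 2 <= m:
        b += 1
    # now b(b-1)/2 <= m < b(b+1)/2
    r = m - b * (b - 1) // 2
    deg = np.zeros(n, dtype=int)
    deg[:b] = b - 1
    deg[:r] += 1
    if r > 0:
        deg[b] = r
    return deg


def max_degree_variance(n: int, m: int) -> float:
    """Maximum population degree variance over simple graphs with (n, m).

    Maximum of the quasi-complete construction and the quasi-star (its
    complement at n(n-1)/2 - m links; complementation maps degrees
    k -> n-1-k and preserves the variance).
    """
    pairs = n * (n - 1) // 2
    if not 0 <= m <= pairs:
        raise ValueError(f"m={m} infeasible for n={n}")
    v_qc = _int_population_variance(_quasi_complete_degrees(n, m))
    v_qs = _int_population_variance((n - 1) - _quasi_complete_degrees(n, pairs - m))
    return max(v_qc, v_qs)


def normalised_degree_variance(g: BinaryGraph) -> float:
    """Degree variance divided by the maximum achievable at the same (n, m)."""
    m = g.m
    if m == 0:
        raise ValueError("normalised degree variance undefined for empty graph")
    vmax = max_degree_variance(g.n, m)
    if vmax == 0.0:
        # only complete/empty graphs; variance is 0 there as well
        return 0.0
    return degree_variance(g) / vmax


def hierarchical_complexity(
    g: BinaryGraph,
    nodes: Sequence[int] | None = None,
    *,
    rescale_degrees: bool = False,
) -> float:
    """Hierarchical complexity R over ``nodes`` (default: all nodes).

    For each degree k shared by at least two nodes of the subset, every
    such node contributes its ascending neighbour-degree sequence
    s_i(1) <= ... <= s_i(k); R_k averages over the k positions the sample
    variance (denominator |C_k| - 1) of {s_i(p)}; R is the mean of R_k
    over qualifying degrees, or 0 when none qualifies.

    Degrees and neighbourhoods always come from the full graph: a node
    subset (a tier) is a grouping of nodes, not an induced subgraph.
    With ``rescale_degrees`` the neighbour degrees are divided by (n - 1)
    before taking variances, giving a size-independent variant.
    """
    k = degree_sequence(g)
    subset = np.arange(g.n) if nodes is None else np.asarray(nodes, dtype=int)
    scale = 1.0 / (g.n - 1) if rescale_degrees else 1.0
    r_values = []
    for deg in np.unique(k[subset]):
        if deg < 1:
            continue
        members = subset[k[subset] == deg]
        if members.size < 2:
            continue
        seqs = np.empty((members.size, deg), dtype=float)
        for row, i in enumerate(members):
            seqs[row] = np.sort(k[np.flatnonzero(g.adjacency[i])]) * scale
        r_values.append(float(np.var(seqs, axis=0, ddof=1).sum() / deg))
    return float(np.mean(r_values)) if r_values else 0.0


@dataclass(frozen=True)
class GlobalMetrics:
    """Subject-level global metrics.

    Density and mean weight come from the unthresholded weighted network
    (density would otherwise be fixed by the threshold); clustering,
    normalised degree variance and hierarchical complexity from the
    binarised graph at the configured proportional density.
    """

    density: float
    mean_weight: float
    clustering: float
    norm_degree_variance: float
    hierarchical_complexity: float


def global_metrics(c: ConnectomeMatrix, density: float = 0.25) -> GlobalMetrics:
    """Compute the global metric panel at the given threshold (default 25%)."""
    g = threshold_to_density(c, density)
    return GlobalMetrics(
        density=network_density(c),
        mean_weight=_mean_weight(c),
        clustering=average_clustering(g),
        norm_degree_variance=normalised_degree_variance(g),
        hierarchical_complexity=hierarchical_complexity(g),
    )
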