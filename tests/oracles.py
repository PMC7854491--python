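"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (exhaustive enumeration,
direct formula evaluation, generic convex optimisation) and never calls
the implementation paths it checks.
"""

from __future__ import annotations

import itertools
from statistics import variance

import numpy as np


def clustering_by_triads(adj: np.ndarray) -> list[float]:
    """Local clustering per node by explicit neighbour-pair enumeration."""
    n = adj.shape[0]
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        out.append(2.0 * links / (k * (k - 1)))
    return out


def hierarchical_complexity_bruteforce(
    adj: np.ndarray, subset=None
) -> float:
    """R by direct loops over degree classes and sequence positions."""
    n = adj.shape[0]
    deg = [int(adj[i].sum()) for i in range(n)]
    nodes = list(range(n)) if subset is None else list(subset)
    r_values = []
    for k in sorted({deg[i] for i in nodes}):
        if k < 1:
            continue
        members = [i for i in nodes if deg[i] == k]
        if len(members) < 2:
            continue
        seqs = [
            sorted(deg[j] for j in range(n) if adj[i, j]) for i in members
        ]
        total = 0.0
        for pos in range(k):
            total += variance([s[pos] for s in seqs])
        r_values.append(total / k)
    return sum(r_values) / len(r_values) if r_values else 0.0


def max_degree_variance_by_enumeration(n: int) -> dict[int, float]:
    """Maximum population degree variance per edge count, all graphs on n nodes.

    Vectorised over all 2^C(n,2) labelled graphs (n <= 7 is practical).
    """
    pairs = list(itertools.combinations(range(n), 2))
    n_pairs = len(pairs)
    incidence = np.zeros((n_pairs, n), dtype=np.float32)
    for b, (i, j) in enumerate(pairs):
        incidence[b, i] = incidence[b, j] = 1.0
    best: dict[int, float] = {}
    chunk = 1 << 18
    for start in range(0, 1 << n_pairs, chunk):
        codes = np.arange(start, min(start + chunk, 1 << n_pairs),
                          dtype=np.int64)
        bits = ((codes[:, None] >> np.arange(n_pairs)) & 1).astype(np.float32)
        degs = bits @ incidence
        var = degs.var(axis=1)
        ms = bits.sum(axis=1).astype(int)
        for m in np.unique(ms):
            v = float(var[ms == m].max())
            if v > best.get(int(m), -1.0):
                best[int(m)] = v
    return best


def ranksum_exact_pvalue(x, y) -> float:
    """Two-sided exact rank-sum p by enumeration of all rank splits."""
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    dist = []
    for subset in itertools.combinations(range(len(pooled)), n1):
        sel = set(subset)
        xs = [pooled[i] for i in sel]
        ys = [pooled[i] for i in range(len(pooled)) if i not in sel]
        dist.append(sum(1 for a in xs for b in ys if a > b))
    dist = np.array(dist)
    p = 2.0 * min((dist <= u_obs).mean(), (dist >= u_obs).mean())
    return min(p, 1.0)


def signedrank_exact_pvalue(diffs) -> float:
    """Two-sided exact signed-rank p by enumeration of all sign patterns."""
    d = [v for v in diffs if v != 0]
    absd = [abs(v) for v in d]
    assert len(set(absd)) == len(absd), "oracle requires untied |differences|"
    n = len(d)
    ranks = {v: r for r, v in enumerate(sorted(absd), start=1)}
    w_obs = sum(ranks[abs(v)] for v in d if v > 0)
    rank_list = sorted(ranks.values())
    dist = []
    for signs in itertools.product((0, 1), repeat=n):
        dist.append(sum(r for r, s in zip(rank_list, signs) if s))
    dist = np.array(dist)
    p = 2.0 * min((dist <= w_obs).mean(), (dist >= w_obs).mean())
    return min(p, 1.0)


def pearson_by_formula(x, y) -> float:
    """Textbook Pearson r: covariance over the product of SDs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def svr_optimal_objective(X, y, lam, eps) -> float:
    """Optimal value of mean eps-insensitive loss + (lam/2)||w||^2.

    Solved as the slack-variable QP with scipy SLSQP (analytic jacobians);
    a generic convex optimiser entirely independent of the SGD path.
    """
    from scipy.optimize import minimize

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, m = X.shape
    nv = m + 1 + n  # w, b, slacks
    J1 = np.hstack([X, np.ones((n, 1)), np.eye(n)])
    J2 = np.hstack([-X, -np.ones((n, 1)), np.eye(n)])
    J3 = np.hstack([np.zeros((n, m + 1)), np.eye(n)])
    cons = [
        {"type": "ineq",
         "fun": lambda z: z[m + 1:] + eps - (y - (X @ z[:m] + z[m])),
         "jac": lambda z: J1},
        {"type": "ineq",
         "fun": lambda z: z[m + 1:] + eps + (y - (X @ z[:m] + z[m])),
         "jac": lambda z: J2},
        {"type": "ineq", "fun": lambda z: z[m + 1:], "jac": lambda z: J3},
    ]
    z0 = np.zeros(nv)
    z0[m] = np.median(y)
    z0[m + 1:] = np.abs(y - np.median(y)) + eps
    res = minimize(
        lambda z: z[m + 1:].mean() + 0.5 * lam * z[:m] @ z[:m],
        z0,
        jac=lambda z: np.concatenate([lam * z[:m], [0.0], np.full(n, 1.0 / n)]),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-16},
    )
    w, b = res.x[:m], res.x[m]
    resid = y - (X @ w + b)
    return float(np.maximum(np.abs(resid) - eps, 0).mean() + 0.5 * lam * w @ w)


def ranksum_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the Mann-Whitney U statistic.

    counts[u] = number of rank arrangements with U = u, by the standard
    lattice recurrence f(a, b, u) = f(a-1, b, u-b) + f(a, b-1, u).
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(a: int, b: int) -> tuple:
        if a == 0 or b == 0:
            return (1,)
        fa = f(a - 1, b)  # largest element in group 1: beats all b others
        fb = f(a, b - 1)  # largest element in group 2
        out = [0] * (a * b + 1)
        for u, c in enumerate(fa):
            out[u + b] += c
        for u, c in enumerate(fb):
            out[u] += c
        return tuple(out)

    return np.array(f(n1, n2), dtype=float)


def signedrank_w_distribution(n: int) -> np.ndarray:
    """Exact null distribution of W+ (sum of positive-sign ranks).

    counts[w] = number of sign patterns with W+ = w; generating function
    product over ranks r of (1 + x^r).
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        nxt = counts.copy()
        nxt[r:] += counts[:-r] if r > 0 else counts
        counts = nxt
    return counts


def twosided_p_from_distribution(dist: np.ndarray, stat: int) -> float:
    """2 * min(lower tail, upper tail), capped at 1."""
    total = dist.sum()
    lower = dist[: stat + 1].sum() / total
    upper = dist[stat:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def ranksum_input_with_u(n1: int, n2: int, u: int):
    """A tie-free sample pair whose Mann-Whitney U (x over y) equals u."""
    assert 0 <= u <= n1 * n2
    y = list(range(1, n2 + 1))
    x = []
    r = u
    for i in range(n1):
        g = min(n2, r)
        r -= g
        x.append(g + (i + 1) / (n1 + 1))
    assert r == 0
    return x, y


def signedrank_diffs_with_w(n: int, w: int):
    """Differences with untied |d| = 1..n whose positive-rank sum is w."""
    total = n * (n + 1) // 2
    assert 0 <= w <= total
    signs = {}
    r = w
    for rank in range(n, 0, -1):
        if r >= rank:
            signs[rank] = +1
            r -= rank
        else:
            signs[rank] = -1
    assert r == 0
    return [signs[rank] * rank for rank in range(1, n + 1)]
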