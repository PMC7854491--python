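"""Voxel-wise lesion-indicator association mapping.

Co-registered binary WMH masks are stacked into a subject x voxel matrix
cropped to the bounding box of the intracranial volume (ICV).  Three kinds
of maps are derived from the stack:

* subgroup WMH probability maps (voxelwise lesion frequency);
* voxel-wise nonparametric group comparisons (rank-sum for two groups,
  Kruskal-Wallis for more) with Benjamini-Hochberg FDR across the tested
  voxels;
* B maps from a ridge-penalised linear support vector regression fitted by
  seeded stochastic gradient descent: predictors are the raw 0/1 voxel
  columns plus standardised age and sex, the outcome is a disease
  indicator or a global network measure, and the per-voxel coefficient B
  is in outcome units per lesion presence (non-standardised), positive
  where lesion presence associates with a higher outcome.

Voxels constant across subjects carry no information: they are excluded
from testing and from the FDR family, and their B is fixed at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numba
import numpy as np

from .lesion_tier import BinaryMask
from .stats import TestResult, bh_fdr, kruskal_wallis, rank_sum_test

__all__ = [
    "VoxelStack",
    "stack_masks",
    "subgroup_probability_map",
    "dichotomise",
    "VoxelTestMaps",
    "voxelwise_group_test",
    "SvrFit",
    "fit_svr_sgd",
    "svr_objective",
    "SvrMap",
    "fit_voxelwise_svr",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoxelStack:
    """Subject x voxel matrix of binary lesion indicators.

    Columns are the voxels inside the ICV bounding box (half-open, 0-based
    index ranges per axis), flattened in C order.
    """

    data: np.ndarray  # (n_subjects, n_voxels) uint8
    crop_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    subject_ids: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def box_shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in self.crop_box)  # type: ignore[return-value]

    def embed(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Re-embed a per-voxel vector into the full grid."""
        values = np.asarray(values, dtype=float)
        out = np.full(self.grid_shape, fill, dtype=float)
        sl = tuple(slice(a, b) for a, b in self.crop_box)
        out[sl] = values.reshape(self.box_shape)
        return out

    def unstack(self, row: int) -> np.ndarray:
        """Row back to a full-grid boolean mask (zero-padded outside the box)."""
        return self.embed(self.data[row], fill=0.0) > 0.5


def stack_masks(masks: Sequence[BinaryMask], icv: BinaryMask,
                subject_ids: Sequence[str] | None = None) -> VoxelStack:
    """Stack WMH masks cropped to the ICV bounding box.

    The crop box is the minimal axis-aligned box containing all
    ICV-positive voxels.  Lesion voxels outside the box (outside the
    skull) would be silently dropped and are therefore warned about.
    """
    if not masks:
        raise ValueError("no masks given")
    if not icv.grid.any():
        raise ValueError("empty ICV mask")
    for m in masks:
        if m.grid.shape != icv.grid.shape:
            raise ValueError("mask grid shape differs from ICV grid")
    box = []
    for axis in range(3):
        proj = icv.grid.any(axis=tuple(a for a in range(3) if a != axis))
        nz = np.flatnonzero(proj)
        box.append((int(nz.min()), int(nz.max()) + 1))
    sl = tuple(slice(a, b) for a, b in box)
    rows = []
    for i, m in enumerate(masks):
        if m.grid.sum() != m.grid[sl].sum():
            log.warning("mask %d has lesion voxels outside the ICV bounding box", i)
        rows.append(m.grid[sl].astype(np.uint8).ravel())
    ids = tuple(subject_ids) if subject_ids is not None else tuple(
        str(i) for i in range(len(masks)))
    return VoxelStack(
        data=np.stack(rows), crop_box=tuple(box),  # type: ignore[arg-type]
        grid_shape=icv.grid.shape, affine=np.asarray(icv.affine),
        subject_ids=ids,
    )


def subgroup_probability_map(
    stack: VoxelStack, members: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Voxelwise lesion frequency over a subject subset, on the full grid."""
    idx = np.asarray(members)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty subgroup")
    freq = stack.data[idx].mean(axis=0)
    return stack.embed(freq, fill=0.0)


def dichotomise(values: Sequence[float], rule: str = "median") -> np.ndarray:
    """Split a continuous indicator into subgroups.

    ``median``: <= sample median -> "low", above -> "high" (the median is
    taken in the analysed sample).  ``quartiles``: four groups "q1".."q4"
    at the 25/50/75 empirical percentiles (linear-interpolation quantiles),
    boundary values to the lower group.
    """
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 4:
        raise ValueError("need at least 4 finite values")
    if np.ptp(v[np.isfinite(v)]) == 0:
        raise ValueError("constant vector cannot be dichotomised")
    if rule == "median":
        med = np.median(v[np.isfinite(v)])
        return np.where(v <= med, "low", "high")
    if rule == "quartiles":
        cuts = np.quantile(v[np.isfinite(v)], [0.25, 0.5, 0.75])
        labels = np.full(v.shape, "q4", dtype=object)
        labels[v <= cuts[2]] = "q3"
        labels[v <= cuts[1]] = "q2"
        labels[v <= cuts[0]] = "q1"
        return labels.astype(str)
    raise ValueError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class VoxelTestMaps:
    """Voxel-wise test output re-embedded in the full grid.

    ``statistic`` and ``p`` are NaN outside the box and at untested
    (constant) voxels; ``passed`` flags the BH-surviving voxels.
    """

    statistic: np.ndarray
    p: np.ndarray
    passed: np.ndarray
    threshold_p: float
    n_tested: int
    method: str


def _binary_group_test(
    counts: tuple[int, ...], sizes: tuple[int, ...], method: str
) -> TestResult:
    """Run the group test on a binary voxel summarised by per-group 1-counts."""
    groups = [
        np.concatenate([np.ones(c), np.zeros(n - c)])
        for c, n in zip(counts, sizes)
    ]
    if method == "ranksum":
        return rank_sum_test(groups[0], groups[1])
    return kruskal_wallis(groups)


def voxelwise_group_test(
    stack: VoxelStack,
    groups: Sequence[str],
    test: str = "ranksum",
    q: float = 0.05,
) -> VoxelTestMaps:
    """Voxel-wise rank-sum / Kruskal-Wallis comparison of lesion maps.

    Constant voxels are excluded from testing and from the BH family.
    Binary columns with identical per-group lesion counts share one
    p-value, so tests are computed once per distinct count pattern.
    """
    labels = np.asarray(groups)
    if labels.size != stack.n_subjects:
        raise ValueError("group labels must match the number of subjects")
    uniq = [u for u in dict.fromkeys(labels.tolist())]
    if test == "ranksum" and len(uniq) != 2:
        raise ValueError("rank-sum test requires exactly two groups")
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    sizes = tuple(int((labels == u).sum()) for u in uniq)
    if any(s < 2 for s in sizes):
        raise ValueError("every group needs at least 2 subjects")

    data = stack.data
    counts = np.stack([data[labels == u].sum(axis=0) for u in uniq])  # g x vox
    total = data.sum(axis=0)
    testable = (total > 0) & (total < stack.n_subjects)
    n_vox = data.shape[1]
    stat = np.full(n_vox, np.nan)
    pvals = np.full(n_vox, np.nan)

    cache: dict[tuple[int, ...], TestResult] = {}
    for j in np.flatnonzero(testable):
        key = tuple(int(c) for c in counts[:, j])
        res = cache.get(key)
        if res is None:
            res = _binary_group_test(key, sizes, test)
            cache[key] = res
        stat[j] = res.statistic
        pvals[j] = res.p_value

    tested = np.flatnonzero(testable)
    passed = np.zeros(n_vox, dtype=bool)
    threshold = 0.0
    if tested.size:
        fdr = bh_fdr(pvals[tested], q=q)
        passed[tested] = fdr.rejected
        threshold = fdr.threshold_p
    return VoxelTestMaps(
        statistic=stack.embed(stat),
        p=stack.embed(pvals),
        passed=stack.embed(passed.astype(float), fill=0.0) > 0.5,
        threshold_p=threshold,
        n_tested=int(tested.size),
        method=test,
    )


# ---------------------------------------------------------------------------
# Ridge-penalised epsilon-insensitive SVR fitted by SGD


def svr_objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float,
    lam: float, epsilon: float,
) -> float:
    """Mean epsilon-insensitive loss plus (lam/2)||w||^2 (intercept free)."""
    resid = y - (X @ w + b)
    loss = np.maximum(np.abs(resid) - epsilon, 0.0)
    return float(loss.mean() + 0.5 * lam * float(w @ w))


@numba.njit(cache=False)
def _sgd_chunk(X, y, lam, eps, order, t_start, t0, w, b, w_avg, b_avg,
               avg_count, avg_start):  # pragma: no cover - jitted
    """One chunk of per-sample subgradient steps with running tail average.

    Step size 1/(lam (t + t0)) at global step t; from step ``avg_start``
    on, the iterates accumulate into the running average (w_avg, b_avg).
    Mutates w and w_avg in place; returns (b, b_avg, avg_count).
    """
    n, p = X.shape
    for idx in range(order.shape[0]):
        t = t_start + idx
        i = order[idx]
        eta = 1.0 / (lam * (t + t0))
        pred = b
        for j in range(p):
            pred += X[i, j] * w[j]
        r = y[i] - pred
        shrink = 1.0 - eta * lam
        if shrink < 0.0:
            shrink = 0.0
        if r > eps:
            for j in range(p):
                w[j] = shrink * w[j] + eta * X[i, j]
            b += eta
        elif r < -eps:
            for j in range(p):
                w[j] = shrink * w[j] - eta * X[i, j]
            b -= eta
        else:
            for j in range(p):
                w[j] = shrink * w[j]
        if t >= avg_start:
            avg_count += 1
            for j in range(p):
                w_avg[j] += (w[j] - w_avg[j]) / avg_count
            b_avg += (b - b_avg) / avg_count
    return b, b_avg, avg_count


@dataclass
class SvrFit:
    w: np.ndarray
    intercept: float
    objective: float
    trace: tuple[float, ...]
    epsilon: float = 0.0
    converged: bool = False
    n_epochs: int = 0


def fit_svr_sgd(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    epsilon: float,
    seed: int,
    n_epochs: int = 300,
    tol: float = 1e-6,
    avg_fraction: float = 0.5,
    eta0: float = 0.1,
    n_checkpoints: int = 40,
) -> SvrFit:
    """Minimise mean eps-insensitive loss + (lam/2)||w||^2 by seeded SGD.

    Per-sample subgradient steps with the strongly-convex decaying
    schedule eta_t = 1/(lam (t + t0)) (t0 set so the first step is
    ``eta0``), plus tail averaging over the final ``avg_fraction`` of the
    steps.  Averaging removes the stochastic oscillation around the
    optimum, so the suboptimality decays like 1/T and small instances
    reach optimiser-grade accuracy with enough epochs.  The trace records
    the averaged iterate's objective at evenly spaced checkpoints;
    convergence is declared when its last relative change is below
    ``tol``.  The fit is a pure function of (inputs, seed).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("outcome length must match number of rows")
    if n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    rng = np.random.default_rng(seed)
    total = n_epochs * n
    avg_start = int((1.0 - avg_fraction) * total)
    t0 = 1.0 / (lam * eta0)
    w = np.zeros(p)
    b = float(np.median(y))
    w_avg = np.zeros(p)
    b_avg = 0.0
    count = 0
    chunk_epochs = max(1, n_epochs // n_checkpoints)
    trace = [svr_objective(X, y, w, b, lam, epsilon)]
    epoch = 0
    t_global = 0
    last_chunk = chunk_epochs
    while epoch < n_epochs:
        this = min(chunk_epochs, n_epochs - epoch)
        order = np.concatenate(
            [rng.permutation(n) for _ in range(this)]).astype(np.int64)
        b, b_avg, count = _sgd_chunk(
            X, y, lam, epsilon, order, t_global, t0, w, b, w_avg, b_avg,
            count, avg_start)
        epoch += this
        t_global += order.size
        last_chunk = this
        if count > 0:
            trace.append(svr_objective(X, y, w_avg, b_avg, lam, epsilon))
    if count == 0:
        w_avg, b_avg = w, b
        trace.append(svr_objective(X, y, w_avg, b_avg, lam, epsilon))
    final = trace[-1]
    # convergence: per-epoch relative objective change below tol
    converged = (
        len(trace) >= 2
        and abs(trace[-1] - trace[-2]) / max(last_chunk, 1)
        <= tol * max(abs(final), 1e-12)
    )
    return SvrFit(
        w=w_avg, intercept=float(b_avg), objective=final, trace=tuple(trace),
        epsilon=epsilon, converged=converged, n_epochs=n_epochs,
    )


@dataclass(frozen=True)
class SvrMap:
    """Voxel-wise B map and covariate coefficients from one SVR fit."""

    b_map: np.ndarray  # full grid; NaN outside the box, 0 at constant voxels
    covariate_coefs: dict[str, float]
    intercept: float
    epsilon: float
    objective: float
    trace: tuple[float, ...]


def fit_voxelwise_svr(
    stack: VoxelStack,
    outcome: Sequence[float],
    covariates: np.ndarray | None,
    lam: float = 1.0 / 47.0,
    epsilon: float | str = "auto",
    seed: int = 0,
    covariate_names: Sequence[str] = ("age", "sex"),
    n_epochs: int = 300,
    tol: float = 1e-6,
) -> SvrMap:
    """Fit one linear SVR of an outcome on the lesion stack plus covariates.

    Voxel predictors stay raw 0/1 so B is in outcome units per lesion
    presence; covariates (age, sex) are standardised and penalised like
    any other predictor; the intercept is unpenalised.  ``epsilon="auto"``
    sets the insensitivity margin to IQR(outcome)/13.49.  Constant voxels
    are dropped from the fit and their B forced to 0.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    if y.size != stack.n_subjects:
        raise ValueError("outcome length must match number of subjects")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outcome")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome")
    if stack.n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if epsilon == "auto":
        q75, q25 = np.percentile(y, [75, 25])
        eps = float(q75 - q25) / 13.49
    else:
        eps = float(epsilon)

    data = stack.data
    total = data.sum(axis=0)
    varying = (total > 0) & (total < stack.n_subjects)
    Xvox = data[:, varying].astype(float)
    blocks = [Xvox]
    names: list[str] = []
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != stack.n_subjects:
            raise ValueError("covariate rows must match number of subjects")
        sd = cov.std(axis=0)
        sd[sd == 0] = 1.0
        blocks.append((cov - cov.mean(axis=0)) / sd)
        names = list(covariate_names)[: cov.shape[1]]
    X = np.hstack(blocks)
    fit = fit_svr_sgd(X, y, lam=lam, epsilon=eps, seed=seed,
                      n_epochs=n_epochs, tol=tol)
    n_vox = data.shape[1]
    b_flat = np.zeros(n_vox)
    b_flat[varying] = fit.w[: int(varying.sum())]
    cov_coefs = {
        name: float(c)
        for name, c in zip(names, fit.w[int(varying.sum()):])
    }
    return SvrMap(
        b_map=stack.embed(b_flat),
        covariate_coefs=cov_coefs,
        intercept=fit.intercept,
        epsilon=eps,
        objective=fit.objective,
        trace=tuple(fit.trace),
    )
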