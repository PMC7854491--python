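"""Connectome data model, file I/O and proportional thresholding.

A structural connectome is represented as a symmetric weighted adjacency
matrix over a fixed grey-matter parcellation (by default the 83-region
Desikan-Killiany scheme: 68 cortical and 14 subcortical regions plus the
brainstem).  Link weights are mean fractional anisotropy (FA) values along
the connecting white-matter tracts, hence dimensionless and bounded in
[0, 1].  Graph-theoretic metrics other than density and mean weight are
computed on binary graphs obtained by proportional thresholding: keeping
the strongest links up to a target density.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: relative asymmetry below this is treated as numerical noise and averaged out
ASYMMETRY_TOL = 1e-8


def _as_labels(labels: Sequence[str], n: int) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    return labels


@dataclass(frozen=True)
class ConnectomeMatrix:
    """Symmetric FA-weighted adjacency matrix with region labels.

    Invariants (enforced on construction): square with n >= 3, zero
    diagonal, non-negative weights, symmetric.  Asymmetry up to
    :data:`ASYMMETRY_TOL` (relative to the largest weight) is averaged
    out; anything larger is an error.
    """

    weights: np.ndarray
    labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"non-square matrix of shape {w.shape}")
        n = w.shape[0]
        if n < 3:
            raise ValueError("connectome needs at least 3 nodes")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite weights")
        scale = max(float(np.abs(w).max()), 1.0)
        asym = float(np.abs(w - w.T).max())
        if asym > ASYMMETRY_TOL * scale:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:g})")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        if w.min() < 0:
            raise ValueError("negative weights")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", _as_labels(self.labels, n))

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Unweighted graph, usually the thresholded support of a connectome."""

    adjacency: np.ndarray
    labels: tuple[str, ...]
    target_density: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"non-square adjacency of shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        a = a.astype(np.int8)
        if (a != a.T).any():
            raise ValueError("adjacency not symmetric")
        np.fill_diagonal(a, 0)
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "labels", _as_labels(self.labels, a.shape[0]))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def m(self) -> int:
        """Number of links (sum of the upper triangle)."""
        return int(np.triu(self.adjacency, 1).sum())


@dataclass
class Cohort:
    """Ordered collection of connectomes sharing one parcellation."""

    members: list[ConnectomeMatrix]
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.members:
            ref = self.members[0].labels
            for c in self.members:
                if c.labels != ref:
                    raise ValueError(
                        f"subject {c.subject_id!r} uses a different parcellation"
                    )

    @property
    def labels(self) -> tuple[str, ...]:
        return self.members[0].labels

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


# ---------------------------------------------------------------------------
# I/O


def read_labels(path: str | Path) -> tuple[str, ...]:
    """Read region names, one per line (UTF-8)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return tuple(s.strip() for s in lines if s.strip())


def read_connectome(
    path: str | Path,
    labels_path: str | Path | None = None,
    *,
    labels: Sequence[str] | None = None,
    subject_id: str | None = None,
    allow_out_of_range: bool = False,
) -> ConnectomeMatrix:
    """Read an n x n weighted matrix (TSV or CSV) into a ConnectomeMatrix.

    FA weights are expected in [0, 1]; values outside are rejected unless
    ``allow_out_of_range`` is set (guards against unit mix-ups such as
    streamline counts).  Either ``labels_path`` or ``labels`` must be given.
    """
    df = pd.read_csv(path, header=None, sep=None, engine="python")
    w = df.to_numpy(dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"non-square matrix of shape {w.shape} in {path}")
    if not allow_out_of_range and (w.min() < 0 or w.max() > 1):
        raise ValueError(
            f"weights outside [0, 1] in {path}; FA weights are bounded "
            "(pass allow_out_of_range=True to override)"
        )
    if labels is None:
        if labels_path is None:
            raise ValueError("either labels_path or labels is required")
        labels = read_labels(labels_path)
    if subject_id is None:
        subject_id = Path(path).stem
    return ConnectomeMatrix(weights=w, labels=labels, subject_id=subject_id)


def write_connectome(c: ConnectomeMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the weight matrix as a plain TSV/CSV (no header/index)."""
    buf = io.StringIO()
    np.savetxt(buf, c.weights, delimiter=sep, fmt="%.8g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_labels(labels: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(labels) + "\n", encoding="utf-8")


def read_cohort(
    manifest_path: str | Path, labels_path: str | Path
) -> dict[str, Cohort]:
    """Read a cohort manifest CSV (subject_id, group, matrix_path).

    Relative matrix paths are resolved against the manifest's directory.
    Returns one :class:`Cohort` per distinct group, keyed by group label.
    """
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "matrix_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = Path(manifest_path).parent
    labels = read_labels(labels_path)
    cohorts: dict[str, Cohort] = {}
    for group, rows in manifest.groupby("group", sort=False):
        members = [
            read_connectome(
                base / str(r.matrix_path), labels=labels, subject_id=str(r.subject_id)
            )
            for r in rows.itertuples()
        ]
        cohorts[str(group)] = Cohort(members=members, group_label=str(group))
    return cohorts


# ---------------------------------------------------------------------------
# Elementary quantities


def network_density(g: ConnectomeMatrix | BinaryGraph) -> float:
    """Fraction of realised links: m / (n(n-1)/2).

    For weighted matrices a link is any strictly positive weight; computed
    on the unthresholded network this is the subject-level density.
    """
    if isinstance(g, BinaryGraph):
        mat = g.adjacency
    else:
        mat = g.weights
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    m = int((mat[iu] > 0).sum())
    return m / (n * (n - 1) / 2)


def mean_weight(c: ConnectomeMatrix) -> float:
    """Mean FA over realised links (strictly positive upper-triangle weights)."""
    iu = np.triu_indices(c.n, k=1)
    w = c.weights[iu]
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("graph has no links")
    return float(w.mean())


def threshold_to_density(c: ConnectomeMatrix, d: float) -> BinaryGraph:
    """Proportional threshold: keep the floor(d * n(n-1)/2) strongest links.

    Ties at the cut are broken deterministically by ascending (row, column)
    index so results are reproducible across platforms.  ``d`` must not
    exceed the unthresholded density.
    """
    if not 0 < d <= 1:
        raise ValueError(f"target density must be in (0, 1], got {d}")
    avail = network_density(c)
    if d > avail + 1e-12:
        raise ValueError(f"target density {d} exceeds available density {avail:.4f}")
    n = c.n
    iu, ju = np.triu_indices(n, k=1)
    w = c.weights[iu, ju]
    m_star = math.floor(d * n * (n - 1) / 2)
    # primary key: weight descending; then row, column ascending
    order = np.lexsort((ju, iu, -w))[:m_star]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[order], ju[order]] = 1
    adj = adj | adj.T
    return BinaryGraph(adjacency=adj, labels=c.labels, target_density=d)


def binarise(c: ConnectomeMatrix) -> BinaryGraph:
    """Unthresholded support: a link wherever the weight is positive."""
    adj = (c.weights > 0).astype(np.int8)
    return BinaryGraph(adjacency=adj, labels=c.labels, target_density=None)


def degree_sequence(g: BinaryGraph) -> np.ndarray:
    """Integer degrees k_i (row sums of the adjacency)."""
    return g.adjacency.sum(axis=1).astype(int)
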