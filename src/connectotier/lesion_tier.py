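"""Tier-wise white-matter-hyperintensity (WMH) load accounting.

Consumes already co-registered voxel volumes on a shared grid: binary WMH
masks, binary grey-matter (GM) masks, and tier label volumes in which each
voxel carries 0 (background), 1-4 (the tier of the region covering it) or
5 (a not-assigned region whose tier is inconsistent across subjects).
Lesion load in a region is a pure voxel-count ratio,

    WMH% = |WMH intersect region| * 100 / |region|,

so voxel volumes cancel; absolute volumes in ml use the voxel volume from
the affine.  No resampling happens here: grids must match exactly, since
resampling belongs to the upstream registration stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .stats import TestResult, bootstrap_pearson, signed_rank_test
from .tiers import TIERS

__all__ = [
    "BinaryMask",
    "TierLabelVolume",
    "read_binary_mask",
    "read_tier_labels",
    "write_volume",
    "lesion_load_by_region",
    "normal_appearing_gm_percent",
    "tier_probability_map",
    "discretise_tier_probability",
    "compare_native_vs_mapped",
]

NA_LABEL = 5
ALLOWED_LABELS = frozenset({0, 1, 2, 3, 4, NA_LABEL})


def _voxel_volume_ml(affine: np.ndarray) -> float:
    return float(abs(np.linalg.det(affine[:3, :3]))) / 1000.0


@dataclass(frozen=True)
class BinaryMask:
    """Binary voxel mask (WMH, GM or ICV) on a 3D grid."""

    grid: np.ndarray  # bool, 3D
    affine: np.ndarray  # 4x4 voxel-to-world
    voxel_volume: float | None = None  # ml per voxel

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError("mask grid must be 3D")
        if g.dtype != bool:
            vals = np.unique(g)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask values must be 0/1")
            g = g.astype(bool)
        object.__setattr__(self, "grid", g)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)
        vv = self.voxel_volume
        if vv is None:
            vv = _voxel_volume_ml(aff)
        if vv <= 0:
            raise ValueError("voxel volume must be positive")
        object.__setattr__(self, "voxel_volume", float(vv))

    @property
    def volume_ml(self) -> float:
        return float(self.grid.sum()) * self.voxel_volume


@dataclass(frozen=True)
class TierLabelVolume:
    """Integer label volume: 0 background, 1-4 tiers, 5 not-assigned."""

    grid: np.ndarray
    affine: np.ndarray
    voxel_volume: float | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError("label grid must be 3D")
        g = np.rint(g).astype(np.int16)
        if not np.isin(np.unique(g), sorted(ALLOWED_LABELS)).all():
            raise ValueError(f"labels must lie in {sorted(ALLOWED_LABELS)}")
        object.__setattr__(self, "grid", g)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)
        vv = self.voxel_volume
        if vv is None:
            vv = _voxel_volume_ml(aff)
        if vv <= 0:
            raise ValueError("voxel volume must be positive")
        object.__setattr__(self, "voxel_volume", float(vv))


def read_binary_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return BinaryMask(grid=data > 0.5, affine=np.asarray(img.affine))


def read_tier_labels(path: str | Path) -> TierLabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return TierLabelVolume(grid=data, affine=np.asarray(img.affine))


def write_volume(
    data: np.ndarray, affine: np.ndarray, path: str | Path
) -> None:
    """Write a 3D (or 4D) array as NIfTI-1, preserving the affine."""
    nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(str(path))


def _check_grids(*vols) -> None:
    shapes = {v.grid.shape for v in vols}
    if len(shapes) > 1:
        raise ValueError(f"grid shape mismatch: {sorted(shapes)}")


def lesion_load_by_region(
    tiers: TierLabelVolume,
    wmh: BinaryMask,
    region_labels: Sequence[int] = TIERS,
) -> dict[int, float]:
    """WMH load per tier region: 100 * |WMH ∩ region| / |region|.

    Empty regions are reported as NaN (missing), never as zero.
    """
    _check_grids(tiers, wmh)
    out: dict[int, float] = {}
    for lab in region_labels:
        region = tiers.grid == lab
        size = int(region.sum())
        if size == 0:
            out[lab] = float("nan")
            continue
        overlap = int((region & wmh.grid).sum())
        out[lab] = 100.0 * overlap / size
    return out


def normal_appearing_gm_percent(
    tiers: TierLabelVolume,
    gm: BinaryMask,
    wmh: BinaryMask,
    region_labels: Sequence[int] = TIERS,
) -> dict[int, float]:
    """Normal-appearing grey matter per tier: 100 * |GM ∩ region \\ WMH| / |region|."""
    _check_grids(tiers, gm, wmh)
    out: dict[int, float] = {}
    for lab in region_labels:
        region = tiers.grid == lab
        size = int(region.sum())
        if size == 0:
            out[lab] = float("nan")
            continue
        nagm = int((region & gm.grid & ~wmh.grid).sum())
        out[lab] = 100.0 * nagm / size
    return out


def tier_probability_map(cohort_tiers: Sequence[TierLabelVolume]) -> np.ndarray:
    """Voxelwise tier frequency across a cohort: shape (4, *grid), values in [0, 1].

    The four maps plus the background/NA fraction sum to one at every voxel.
    """
    if not cohort_tiers:
        raise ValueError("empty cohort")
    _check_grids(*cohort_tiers)
    shape = cohort_tiers[0].grid.shape
    maps = np.zeros((len(TIERS),) + shape, dtype=float)
    for vol in cohort_tiers:
        for i, t in enumerate(TIERS):
            maps[i] += vol.grid == t
    maps /= len(cohort_tiers)
    return maps


def discretise_tier_probability(
    maps: np.ndarray, affine: np.ndarray
) -> TierLabelVolume:
    """Discretise per-tier probability maps to a label volume.

    Each voxel takes the label (background = remaining probability, or a
    tier) with the highest probability; ties go to the lower label, so a
    tie between tiers prefers the lower tier number.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4 or maps.shape[0] != len(TIERS):
        raise ValueError("expected maps of shape (4, nx, ny, nz)")
    background = 1.0 - maps.sum(axis=0)
    stacked = np.concatenate([background[None], maps], axis=0)
    labels = np.argmax(stacked, axis=0)  # argmax takes the first (lowest) on ties
    return TierLabelVolume(grid=labels, affine=affine)


def compare_native_vs_mapped(
    native: pd.DataFrame,
    mapped: pd.DataFrame,
    value: str = "wmh_percent",
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Matched-pair comparison of per-tier loads: native tiers vs mapped
    "control tiers" in the same subjects.

    Both tables are tidy (subject_id, tier, <value>) over the same subjects
    in the same order.  Per tier: Wilcoxon signed-rank p and the seeded
    bootstrap Pearson correlation between the two load vectors.  When all
    paired differences are zero the signed-rank p is undefined and reported
    as NaN.
    """
    rows = []
    for t in TIERS:
        a = native.loc[native["tier"] == t].set_index("subject_id")[value]
        b = mapped.loc[mapped["tier"] == t].set_index("subject_id")[value]
        if list(a.index) != list(b.index):
            raise ValueError(f"subject mismatch in tier {t}")
        av, bv = a.to_numpy(float), b.to_numpy(float)
        keep = np.isfinite(av) & np.isfinite(bv)
        av, bv = av[keep], bv[keep]
        try:
            test: TestResult | None = signed_rank_test(av, bv)
            p = test.p_value
        except ValueError:
            test, p = None, float("nan")
        try:
            r, lo, hi = bootstrap_pearson(av, bv, n_boot=n_boot, seed=seed)
        except ValueError:
            r = lo = hi = float("nan")
        rows.append({
            "tier": t,
            "n": int(av.size),
            "mean_native": float(av.mean()) if av.size else float("nan"),
            "mean_mapped": float(bv.mean()) if bv.size else float("nan"),
            "signed_rank_p": p,
            "pearson_r": r,
            "r_ci_low": lo,
            "r_ci_high": hi,
        })
    return pd.DataFrame(rows)
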