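"""Seeded generators emulating the study's inputs.

Two generators with known ground truth drive all simulation-based tests:

* two-group connectome cohorts -- subject graphs drawn around a shared
  hub-structured template (link probability proportional to the product
  of heavy-tailed node propensities, FA-like weights coupled to the same
  propensities), with group-level contrasts planted as extra links among
  low-degree nodes (raising density), a weight offset (raising mean FA),
  and degree-preserving edge rewiring (lowering clustering);
* lesion-mask cohorts -- periventricular lesion probability fields
  (Bernoulli sampling of an exponentially decaying rate around a
  ventricle ellipsoid, morphologically closed for contiguity) with one
  planted cluster whose lesion log-odds track a subject-level indicator
  z-score, plus age/sex covariates.

Default dimensions mirror the study scale (83 nodes, 47 + 47 subjects,
48^3 voxel grids); between-subject dispersion of density and mean weight
defaults to the magnitude reported for the study cohorts (SD ~ 2.5-3
percentage points of density, ~ 0.015 of mean FA).  Everything is a pure
function of its spec, whose seed is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import expit, logit

from .graph_core import ConnectomeMatrix, Cohort, write_connectome, write_labels
from .lesion_tier import BinaryMask, TierLabelVolume

__all__ = [
    "ConnectomeSimSpec",
    "LesionSimSpec",
    "generate_connectome_cohorts",
    "generate_lesion_cohort",
    "generate_tier_volume_cohort",
    "atlas_fixture",
    "export_cohorts",
]

_DK_CORTICAL = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)
_DK_SUBCORTICAL = (
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala",
    "accumbens",
)


def atlas_fixture() -> tuple[str, ...]:
    """Deterministic 83-region Desikan-Killiany-style label list.

    68 cortical (34 per hemisphere) and 14 subcortical (7 per hemisphere;
    the ventral diencephalon carries no network node) regions plus the
    brainstem, in stable order.
    """
    labels = []
    for hemi in ("lh", "rh"):
        labels += [f"{hemi}-{name}" for name in _DK_CORTICAL]
    for hemi in ("lh", "rh"):
        labels += [f"{hemi}-{name}" for name in _DK_SUBCORTICAL]
    labels.append("brainstem")
    return tuple(labels)


# ---------------------------------------------------------------------------
# Connectome cohorts


@dataclass(frozen=True)
class ConnectomeSimSpec:
    """Study-scale two-group connectome simulation.

    Group B (the "patient-like" group) receives ``delta_density`` extra
    link probability placed preferentially among low-propensity node
    pairs, ``delta_mean_weight`` added to every link weight, and
    ``clustering_rewire_fraction`` of its links rewired by
    degree-preserving double-edge swaps.
    """

    n_nodes: int = 83
    n_per_group: int = 47
    base_density: float = 0.37
    delta_density: float = 0.04
    base_mean_weight: float = 0.396
    delta_mean_weight: float = 0.02
    clustering_rewire_fraction: float = 0.1
    hubness: float = 0.25          # propensity decay exponent (degree heterogeneity)
    latent_scale: float = 0.25     # spatial decay of link probability (triangles)
    weight_noise_sd: float = 0.03  # per-link FA noise
    weight_degree_coupling: float = 0.03  # hub-edge FA bonus per score SD
    density_jitter_sd: float = 0.025      # between-subject density SD
    mean_weight_jitter_sd: float = 0.015  # between-subject mean-FA SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.base_density < 1:
            raise ValueError("base_density must lie in (0, 1)")
        if self.base_density + self.delta_density >= 1:
            raise ValueError("delta_density pushes density beyond 1")
        if self.n_nodes < 3 or self.n_per_group < 2:
            raise ValueError("infeasible cohort dimensions")


def _edge_probabilities(score: np.ndarray, target_mean: float) -> np.ndarray:
    """Scale clip(c * score, 0, 1) so its mean hits the target density."""
    lo, hi = 0.0, 1.0
    while np.minimum(hi * score, 1.0).mean() < target_mean:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("cannot reach target density")
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if np.minimum(mid * score, 1.0).mean() < target_mean:
            lo = mid
        else:
            hi = mid
    return np.minimum(hi * score, 1.0)


def _double_edge_swaps(adj_w: np.ndarray, n_swaps: int, rng: np.random.Generator) -> None:
    """Degree-preserving rewiring of a weighted symmetric matrix, in place.

    Each swap replaces links a-b, c-d with a-d, c-b (weights carried
    along), skipping proposals that collide with existing links.
    """
    iu, ju = np.nonzero(np.triu(adj_w, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    done = 0
    attempts = 0
    while done < n_swaps and attempts < 50 * max(n_swaps, 1):
        attempts += 1
        e1, e2 = rng.integers(0, len(edges), size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            b, a = a, b
        if len({a, b, c, d}) < 4:
            continue
        if adj_w[a, d] > 0 or adj_w[c, b] > 0:
            continue
        w1, w2 = adj_w[a, b], adj_w[c, d]
        adj_w[a, b] = adj_w[b, a] = 0.0
        adj_w[c, d] = adj_w[d, c] = 0.0
        adj_w[a, d] = adj_w[d, a] = w1
        adj_w[c, b] = adj_w[b, c] = w2
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        done += 1


def _draw_subject(
    probs: np.ndarray,
    score_z: np.ndarray,
    iu: tuple[np.ndarray, np.ndarray],
    n: int,
    mean_w: float,
    spec: ConnectomeSimSpec,
    rng: np.random.Generator,
    extra_probs: np.ndarray | None,
    rewire_fraction: float,
    labels: tuple[str, ...],
    subject_id: str,
) -> ConnectomeMatrix:
    present = rng.random(probs.shape) < probs
    if extra_probs is not None:
        present |= (~present) & (rng.random(probs.shape) < extra_probs)
    n_edges = int(present.sum())
    if n_edges == 0:
        raise ValueError("degenerate subject with no links")
    bonus = spec.weight_degree_coupling * score_z[present]
    bonus -= bonus.mean()  # keep realised mean FA at the subject's target
    w_edges = mean_w + bonus + rng.normal(0.0, spec.weight_noise_sd, n_edges)
    w_edges = np.clip(w_edges, 0.01, 0.99)
    mat = np.zeros((n, n))
    mat[iu[0][present], iu[1][present]] = w_edges
    mat = mat + mat.T
    if rewire_fraction > 0:
        _double_edge_swaps(mat, int(round(rewire_fraction * n_edges / 2)), rng)
    return ConnectomeMatrix(weights=mat, labels=labels, subject_id=subject_id)


def generate_connectome_cohorts(
    spec: ConnectomeSimSpec,
) -> tuple[Cohort, Cohort, dict]:
    """Draw the two cohorts and return them with the ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    if n == 83:
        labels = atlas_fixture()
    else:
        labels = tuple(f"roi{i:03d}" for i in range(n))
    u = np.arange(1, n + 1, dtype=float) ** (-spec.hubness)
    u /= u.mean()
    # shared template: hub propensities plus latent positions; spatial
    # proximity concentrates links locally, giving the excess clustering
    # that degree-preserving rewiring can then destroy
    pos = rng.random((n, 3))
    dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    iu = np.triu_indices(n, 1)
    score = (np.outer(u, u) * np.exp(-dist / spec.latent_scale))[iu]
    log_s = np.log(score)
    score_z = (log_s - log_s.mean()) / log_s.std()
    # extra-link propensity for the patient-like group: inverse degree
    # propensity, so added links land preferentially on low-degree nodes
    inv = 1.0 / np.outer(u, u)[iu]
    inv /= inv.mean()

    def make(group: str, patient_like: bool) -> list[ConnectomeMatrix]:
        members = []
        for s in range(spec.n_per_group):
            d_s = spec.base_density + rng.normal(0.0, spec.density_jitter_sd)
            d_s = float(np.clip(d_s, 0.05, 0.95))
            mw_s = spec.base_mean_weight + rng.normal(0.0, spec.mean_weight_jitter_sd)
            extra = None
            rewire = 0.0
            if patient_like:
                mw_s += spec.delta_mean_weight
                rewire = spec.clustering_rewire_fraction
            probs = _edge_probabilities(score, d_s)
            if patient_like and spec.delta_density > 0:
                # solve the extra-link scale so the expected density added
                # on top of the existing links equals delta_density
                lo, hi = 0.0, 1.0
                while (np.minimum(hi * inv, 1.0) * (1 - probs)).mean() \
                        < spec.delta_density:
                    hi *= 2.0
                    if hi > 1e9:
                        raise ValueError("delta_density infeasible")
                for _ in range(60):
                    mid = (lo + hi) / 2.0
                    if (np.minimum(mid * inv, 1.0) * (1 - probs)).mean() \
                            < spec.delta_density:
                        lo = mid
                    else:
                        hi = mid
                extra = np.minimum(hi * inv, 1.0)
            members.append(
                _draw_subject(
                    probs, score_z, iu, n, mw_s, spec, rng, extra, rewire,
                    labels, f"{group}{s:03d}",
                )
            )
        return members

    cohort_a = Cohort(members=make("ctrl", False), group_label="A")
    cohort_b = Cohort(members=make("pat", True), group_label="B")
    planted = []
    if spec.delta_density != 0:
        planted.append("density")
    if spec.delta_mean_weight != 0:
        planted.append("mean_weight")
    if spec.clustering_rewire_fraction > 0:
        planted.append("clustering")
    truth = {
        "delta_density": spec.delta_density,
        "delta_mean_weight": spec.delta_mean_weight,
        "clustering_rewire_fraction": spec.clustering_rewire_fraction,
        "planted_metrics": planted,
    }
    return cohort_a, cohort_b, truth


def export_cohorts(
    cohort_a: Cohort, cohort_b: Cohort, outdir: str | Path,
    spec: ConnectomeSimSpec | None = None,
) -> Path:
    """Write TSV matrices, a labels file and a manifest CSV (CLI input layout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_labels(cohort_a.labels, outdir / "labels.txt")
    rows = []
    for cohort in (cohort_a, cohort_b):
        for c in cohort:
            fname = f"{c.subject_id}.tsv"
            write_connectome(c, outdir / fname)
            rows.append({
                "subject_id": c.subject_id,
                "group": cohort.group_label,
                "matrix_path": fname,
            })
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    if spec is not None:
        (outdir / "sim_spec.yaml").write_text(yaml.safe_dump(asdict(spec)))
    return outdir / "manifest.csv"


# ---------------------------------------------------------------------------
# Lesion cohorts


@dataclass(frozen=True)
class LesionSimSpec:
    """Periventricular lesion cohort with one indicator-linked cluster.

    The lesion probability field is baseline_rate * exp(-dist/decay)
    restricted to white matter (inside the ICV ellipsoid, outside the
    grey-matter shell and the ventricle); inside the planted spherical
    cluster each subject's lesion log-odds shift by effect_size times the
    subject's indicator z-score.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    ventricle_semiaxes: tuple[float, float, float] = (9.0, 5.0, 5.0)
    icv_semiaxes: tuple[float, float, float] = (21.0, 22.0, 20.0)
    gm_shell_start: float = 0.78   # normalised ellipsoid radius where GM begins
    decay: float = 4.0             # periventricular decay length, voxels
    baseline_rate: float = 0.15    # lesion probability at the ventricle wall
    cluster_center: tuple[int, int, int] = (32, 29, 24)
    cluster_radius: float = 3.0
    effect_size: float = 1.5       # log-odds shift per indicator SD
    n_subjects: int = 47
    age_mean: float = 48.5
    age_sd: float = 13.7
    female_fraction: float = 0.915
    voxel_size_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.baseline_rate > 1:
            raise ValueError("baseline_rate must lie in [0, 1]")
        center = np.array(self.shape) / 2.0
        rel = (np.array(self.cluster_center) - center) / np.array(self.icv_semiaxes)
        if np.sum(rel**2) >= 1.0:
            raise ValueError("planted cluster lies outside the ICV")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semiaxes))
    return r2 <= 1.0


def generate_lesion_cohort(
    spec: LesionSimSpec,
) -> tuple[list[BinaryMask], BinaryMask, BinaryMask, pd.DataFrame, np.ndarray]:
    """Draw WMH masks, ICV and GM masks, the indicator table and truth map.

    The indicator table has columns subject_id, age, sex (1 = female),
    ``indicator`` (the planted z-score driving in-cluster lesion odds) and
    ``null_indicator`` (independent noise, for calibration checks).  The
    truth map is a boolean full-grid array marking the planted voxels.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = tuple(s / 2.0 for s in shape)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])

    icv = _ellipsoid(shape, center, spec.icv_semiaxes)
    grids = np.indices(shape, dtype=float)
    r2 = sum(((g - c) / s) ** 2
             for g, c, s in zip(grids, center, spec.icv_semiaxes))
    gm = icv & (np.sqrt(r2) >= spec.gm_shell_start)
    vent = _ellipsoid(shape, center, spec.ventricle_semiaxes)
    wm = icv & ~gm & ~vent
    dist = ndimage.distance_transform_edt(~vent)
    p0 = np.where(wm, spec.baseline_rate * np.exp(-dist / spec.decay), 0.0)

    cc = np.array(spec.cluster_center, dtype=float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, cc))
    cluster = (d2 <= spec.cluster_radius**2) & wm
    if spec.effect_size != 0 and not cluster.any():
        raise ValueError("planted cluster does not intersect white matter")

    base_logit = logit(np.clip(p0, 1e-6, 1 - 1e-6))
    masks = []
    z = rng.standard_normal(spec.n_subjects)
    ages = rng.normal(spec.age_mean, spec.age_sd, spec.n_subjects)
    sexes = (rng.random(spec.n_subjects) < spec.female_fraction).astype(int)
    null_z = rng.standard_normal(spec.n_subjects)
    structure = ndimage.generate_binary_structure(3, 1)
    for s in range(spec.n_subjects):
        p = p0.copy()
        if spec.effect_size != 0:
            p[cluster] = expit(base_logit[cluster] + spec.effect_size * z[s])
        lesions = rng.random(shape) < p
        if lesions.any():
            lesions = ndimage.binary_closing(lesions, structure=structure)
        lesions &= icv
        masks.append(BinaryMask(grid=lesions, affine=affine))
    table = pd.DataFrame({
        "subject_id": [f"sub{s:03d}" for s in range(spec.n_subjects)],
        "age": ages,
        "sex": sexes,
        "indicator": z,
        "null_indicator": null_z,
    })
    return (
        masks,
        BinaryMask(grid=icv, affine=affine),
        BinaryMask(grid=gm, affine=affine),
        table,
        cluster,
    )


def generate_tier_volume_cohort(
    spec: LesionSimSpec, jitter: float = 1.0,
) -> tuple[list[TierLabelVolume], list[TierLabelVolume]]:
    """Concentric-shell tier label volumes for the tier-load analysis.

    Native volumes jitter the shell boundaries per subject; "mapped
    control tier" volumes use the unjittered template shells for every
    subject, emulating control tiers registered into patient space.
    Tier 1 is the innermost (deep grey matter) shell, tiers 2-4 move
    outward, and an outer cap carries the not-assigned label.
    """
    rng = np.random.default_rng(spec.seed + 1)
    shape = spec.shape
    center = tuple(s / 2.0 for s in shape)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    grids = np.indices(shape, dtype=float)
    rnorm = np.sqrt(sum(((g - c) / s) ** 2
                        for g, c, s in zip(grids, center, spec.icv_semiaxes)))
    vent = _ellipsoid(shape, center, spec.ventricle_semiaxes)

    def shells(cuts: Sequence[float]) -> np.ndarray:
        vol = np.zeros(shape, dtype=np.int16)
        bands = [(cuts[0], cuts[1], 1), (cuts[1], cuts[2], 2),
                 (cuts[2], cuts[3], 3), (cuts[3], cuts[4], 4),
                 (cuts[4], 1.0, 5)]
        for lo, hi, lab in bands:
            vol[(rnorm >= lo) & (rnorm < hi) & ~vent] = lab
        return vol

    base_cuts = (0.0, 0.30, 0.48, 0.64, 0.88)
    scale = jitter * 0.015
    native, mapped = [], []
    for _ in range(spec.n_subjects):
        cuts = [0.0] + [c + rng.normal(0.0, scale) for c in base_cuts[1:]]
        native.append(TierLabelVolume(grid=shells(cuts), affine=affine))
        mapped.append(TierLabelVolume(grid=shells(base_cuts), affine=affine))
    return native, mapped
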