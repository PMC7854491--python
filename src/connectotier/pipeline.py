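"""End-to-end analyses and their report tables.

Three analyses chain the library modules together:

1. group comparison of connectome metrics -- per-subject global and tier
   metrics, Wilcoxon rank-sum per metric, Benjamini-Hochberg FDR across
   the entire joint family of global + tier metrics, Cohen's d, and
   per-tier Pearson correlation of ROI tier-placement counts between
   groups (descriptive, outside the FDR family);
2. tier-wise WMH load -- native tiers vs mapped control tiers, per-tier
   matched-pair signed-rank tests and seeded bootstrap correlations;
3. voxel-wise lesion mapping -- subgroup WMH probability maps,
   voxel-wise rank tests with FDR, and SVR B maps per indicator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graph_core import Cohort, threshold_to_density
from .lesion_tier import BinaryMask, TierLabelVolume, compare_native_vs_mapped
from .lesion_tier import lesion_load_by_region, normal_appearing_gm_percent
from .metrics import global_metrics
from .stats import bh_fdr, cohens_d, rank_sum_test
from .tiers import TIERS, assign_tiers, tier_frequency, tier_metrics
from .tiers import tier_placement_correlation
from .voxel_mapping import VoxelStack, dichotomise, fit_voxelwise_svr
from .voxel_mapping import subgroup_probability_map, voxelwise_group_test

__all__ = [
    "RunConfig",
    "subject_metric_row",
    "cohort_metric_table",
    "run_analysis1",
    "run_analysis2",
    "run_analysis3",
]


@dataclass
class RunConfig:
    """Analysis constants; defaults are the study's stated values."""

    density: float = 0.25        # proportional threshold for binarisation
    q: float = 0.05              # BH false-discovery level
    n_boot: int = 1000           # bootstrap resamples for Pearson CIs
    lam: float = 1.0 / 47.0      # SVR ridge regularisation strength
    seed: int = 0
    svr_epsilon: float | str = "auto"
    svr_n_epochs: int = 300

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def provenance(self) -> dict:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return {
            "config": asdict(self),
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "package_version": __version__,
        }


def subject_metric_row(connectome, density: float = 0.25) -> dict[str, float]:
    """All Table-style metrics for one subject: 5 global + 3 per tier.

    Keys: density, mean_weight, clustering, norm_degree_variance,
    hierarchical_complexity, then tier{t}_avg_degree / _clustering /
    _complexity.  Empty tiers appear as NaN.
    """
    g = threshold_to_density(connectome, density)
    gm = global_metrics(connectome, density)
    assignment = assign_tiers(g)
    tm = tier_metrics(g, assignment)
    row: dict[str, float] = {
        "density": gm.density,
        "mean_weight": gm.mean_weight,
        "clustering": gm.clustering,
        "norm_degree_variance": gm.norm_degree_variance,
        "hierarchical_complexity": gm.hierarchical_complexity,
    }
    for t in TIERS:
        row[f"tier{t}_avg_degree"] = tm.average_degree[t]
        row[f"tier{t}_clustering"] = tm.clustering[t]
        row[f"tier{t}_complexity"] = tm.complexity[t]
    return row


def cohort_metric_table(cohort: Cohort, density: float = 0.25) -> pd.DataFrame:
    rows = []
    for c in cohort:
        row = subject_metric_row(c, density)
        row["subject_id"] = c.subject_id
        row["group"] = cohort.group_label
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def run_analysis1(
    cohort_a: Cohort,
    cohort_b: Cohort,
    config: RunConfig | None = None,
) -> dict:
    """Group comparison of global and tier metrics.

    Returns a dict with the per-metric report (means, SDs, rank-sum p,
    BH pass flag at q, Cohen's d), the two subject-level metric tables,
    and the per-tier placement correlations.  The BH family spans all
    global + tier metrics jointly; metrics with an empty tier in any
    subject drop the missing values pairwise.
    """
    config = config or RunConfig()
    if cohort_a.labels != cohort_b.labels:
        raise ValueError("cohorts use different parcellations")
    tab_a = cohort_metric_table(cohort_a, config.density)
    tab_b = cohort_metric_table(cohort_b, config.density)
    metric_cols = [c for c in tab_a.columns if c != "group"]
    rows = []
    for col in metric_cols:
        x = tab_a[col].dropna().to_numpy(float)
        y = tab_b[col].dropna().to_numpy(float)
        if x.size < 2 or y.size < 2:
            continue
        test = rank_sum_test(x, y)
        rows.append({
            "metric": col,
            "mean_a": x.mean(), "sd_a": x.std(ddof=1),
            "mean_b": y.mean(), "sd_b": y.std(ddof=1),
            "p": test.p_value,
            "cohens_d": cohens_d(x, y) if (x.std(ddof=1) or y.std(ddof=1)) else 0.0,
            "n_a": x.size, "n_b": y.size,
        })
    report = pd.DataFrame(rows)
    fdr = bh_fdr(report["p"].to_numpy(), q=config.q)
    report["bh_pass"] = fdr.rejected

    assign_a = [assign_tiers(threshold_to_density(c, config.density))
                for c in cohort_a]
    assign_b = [assign_tiers(threshold_to_density(c, config.density))
                for c in cohort_b]
    freq_a = tier_frequency(assign_a)
    freq_b = tier_frequency(assign_b)
    correlations = tier_placement_correlation(freq_a, freq_b)
    return {
        "report": report,
        "metrics_a": tab_a,
        "metrics_b": tab_b,
        "tier_frequency_a": freq_a,
        "tier_frequency_b": freq_b,
        "placement_correlation": correlations,
        "bh_threshold_p": fdr.threshold_p,
        "provenance": config.provenance(),
    }


def run_analysis2(
    native_tiers: Sequence[TierLabelVolume],
    mapped_tiers: Sequence[TierLabelVolume],
    wmh_masks: Sequence[BinaryMask],
    gm_masks: Sequence[BinaryMask] | None = None,
    subject_ids: Sequence[str] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Tier-wise WMH (and normal-appearing GM) load, native vs mapped tiers."""
    config = config or RunConfig()
    n = len(wmh_masks)
    if len(native_tiers) != n or len(mapped_tiers) != n:
        raise ValueError("per-subject volume lists must have equal length")
    ids = list(subject_ids) if subject_ids is not None else [
        f"sub{i:03d}" for i in range(n)]

    def load_table(tier_vols) -> pd.DataFrame:
        rows = []
        for sid, tv, wmh, i in zip(ids, tier_vols, wmh_masks, range(n)):
            loads = lesion_load_by_region(tv, wmh)
            nagm = (
                normal_appearing_gm_percent(tv, gm_masks[i], wmh)
                if gm_masks is not None else {t: float("nan") for t in TIERS}
            )
            for t in TIERS:
                rows.append({
                    "subject_id": sid, "tier": t,
                    "wmh_percent": loads[t], "nagm_percent": nagm[t],
                })
        return pd.DataFrame(rows)

    native = load_table(native_tiers)
    mapped = load_table(mapped_tiers)
    comparison = compare_native_vs_mapped(
        native, mapped, "wmh_percent", n_boot=config.n_boot, seed=config.seed)
    out = {
        "native_loads": native,
        "mapped_loads": mapped,
        "comparison": comparison,
        "provenance": config.provenance(),
    }
    if gm_masks is not None:
        out["nagm_comparison"] = compare_native_vs_mapped(
            native, mapped, "nagm_percent", n_boot=config.n_boot,
            seed=config.seed)
    return out


def run_analysis3(
    stack: VoxelStack,
    table: pd.DataFrame,
    indicators: Sequence[str],
    config: RunConfig | None = None,
    outcomes_extra: dict[str, np.ndarray] | None = None,
) -> dict:
    """Voxel-wise lesion-indicator mapping.

    Per indicator: low/high subgroup probability maps, a voxel-wise
    rank-sum comparison with BH-FDR (binary indicators are used as given;
    continuous ones are median-dichotomised in the analysed sample), and
    the SVR B map with age and sex as covariates.  ``outcomes_extra``
    maps additional outcome names (e.g. network global measures) to
    vectors; these get B maps only.
    """
    config = config or RunConfig()
    if len(table) != stack.n_subjects:
        raise ValueError("indicator table rows must match stack subjects")
    covars = table[["age", "sex"]].to_numpy(float)
    results: dict[str, dict] = {}
    for name in indicators:
        if name not in table.columns:
            raise KeyError(f"indicator {name!r} missing from table")
        values = table[name].to_numpy(float)
        uniq = np.unique(values[np.isfinite(values)])
        if uniq.size == 2:
            groups = np.where(values == uniq.max(), "high", "low")
        else:
            groups = dichotomise(values, "median")
        prob_maps = {
            lab: subgroup_probability_map(stack, groups == lab)
            for lab in ("low", "high")
        }
        test_maps = voxelwise_group_test(stack, groups, "ranksum", q=config.q)
        svr = fit_voxelwise_svr(
            stack, values, covars, lam=config.lam, epsilon=config.svr_epsilon,
            seed=config.seed, n_epochs=config.svr_n_epochs,
        )
        results[name] = {
            "groups": groups,
            "probability_maps": prob_maps,
            "test": test_maps,
            "svr": svr,
        }
    for name, values in (outcomes_extra or {}).items():
        svr = fit_voxelwise_svr(
            stack, np.asarray(values, float), covars, lam=config.lam,
            epsilon=config.svr_epsilon, seed=config.seed,
            n_epochs=config.svr_n_epochs,
        )
        results[name] = {"svr": svr}
    return {"indicators": results, "provenance": config.provenance()}
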