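# connectotier

Hierarchical tier analysis of FA-weighted structural connectomes, with
white-matter-hyperintensity (WMH) lesion mapping. The package implements
the analysis chain used to compare brain networks between a patient
cohort (e.g. systemic lupus erythematosus, SLE) and healthy controls and
to relate lesion topography to disease indicators — as a tested,
reusable library with a command-line interface and a synthetic-data
module, so the whole pipeline runs end to end without any private
imaging data.

It is aimed at researchers in structural connectomics and small-vessel
disease imaging who have per-subject connectome matrices (FA-weighted,
Desikan-Killiany-style parcellation), co-registered binary WMH masks,
and a clinical indicator table — or who want to study the statistical
behaviour of this kind of pipeline on simulated cohorts.

## What it computes

**Network metrics.** Each subject's weighted connectome (n×n symmetric,
FA weights in [0, 1]) is thresholded proportionally to a fixed density
(default 25%, keeping the ⌊d·n(n−1)/2⌋ strongest links). On the binary
graph:

- *clustering coefficient* C — the mean local clustering
  C_i = 2t_i / k_i(k_i−1);
- *normalised degree variance* — population variance of the degree
  sequence divided by the maximum achievable at the same (n, m), attained
  by the quasi-star / quasi-complete extremal graphs, so the value lies
  in [0, 1];
- *hierarchical complexity* R — for each degree k shared by ≥ 2 nodes,
  each node contributes its ascending neighbour-degree sequence
  s_i(1) ≤ … ≤ s_i(k); R_k = (1/k) Σ_p Var{s_i(p)} (sample variance),
  and R is the mean of R_k over qualifying degrees. R = 0 exactly when
  same-degree nodes have identical connectivity profiles.

Density and mean FA weight are computed on the unthresholded network.

**Tiers.** Nodes are stratified by quartiles of the subject's maximum
degree: Tier 1 holds nodes with k > 0.75·k_max, Tier 2 those with
0.5·k_max < k ≤ 0.75·k_max, and so on. Per tier: average degree, average
local clustering and within-tier hierarchical complexity (tiers are node
groupings — degrees and neighbourhoods always come from the full graph).

**Statistics.** Wilcoxon rank-sum (exact for small tie-free samples) per
metric, Benjamini–Hochberg FDR at q = 0.05 across the joint metric
family, Cohen's d, per-tier Pearson correlation of ROI tier-placement
counts between groups, matched-pair signed-rank tests for tier-wise WMH
load (WMH% = lesion voxels × 100 / region voxels), and a seeded
1000-resample percentile bootstrap for correlations.

**Voxel-wise lesion mapping.** WMH masks are stacked subject × voxel,
cropped to the intracranial-volume bounding box. Per disease indicator:
subgroup probability maps (median-dichotomised groups), voxel-wise
rank-sum / Kruskal–Wallis tests with voxel-wise FDR, and a B map from a
ridge-penalised linear support vector regression (ε-insensitive loss,
regularisation λ = 1/47, ε = IQR/13.49 by default) fitted by seeded
stochastic gradient descent with tail averaging; age and sex enter as
standardised covariates, voxels stay raw 0/1 so B is in outcome units
per lesion presence.

## Worked example

```python
import connectotier as ct
from connectotier.pipeline import run_analysis1

spec = ct.ConnectomeSimSpec(seed=42)      # 47 + 47 subjects, 83 nodes
controls, patients, truth = ct.generate_connectome_cohorts(spec)
res = run_analysis1(controls, patients)
print(res["report"][["metric", "mean_a", "mean_b", "p", "cohens_d", "bh_pass"]])
```

prints (global rows shown):

```
                 metric  mean_a  mean_b         p  cohens_d  bh_pass
                density  0.3637  0.4063 4.102e-10    -1.658     True
            mean_weight  0.3953  0.4167 2.316e-09    -1.509     True
             clustering  0.4695  0.3988 6.923e-17     5.492     True
hierarchical_complexity   8.129   6.738 5.566e-05    0.9726     True
tier placement correlations: {1: 0.984, 2: 0.972, 3: 0.966, 4: 0.968}
```

The generator planted a +0.04 density contrast, a +0.02 mean-FA
contrast, and 10% degree-preserving rewiring in the patient-like group;
all three planted metrics are recovered after FDR (negative d means the
patient-like group is higher), while the high tier-placement
correlations show the node hierarchy itself stays largely shared —
the same qualitative picture the analysis is designed to expose.

The same chain is available from the shell:

```bash
connectotier simulate-connectomes --out sim --seed 1
connectotier compare-groups --manifest sim/manifest.csv --labels sim/labels.txt --out cmp --seed 1
connectotier simulate-lesions --out siml --seed 2
connectotier voxel-map --masks siml/mask_manifest.csv --icv siml/icv.nii \
    --table siml/indicators.csv --outcome indicator --out vox --seed 3
```

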