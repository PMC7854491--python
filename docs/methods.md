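# Methods

This note records the models, numerical conventions and design choices
behind the package, and what the synthetic cohorts do and do not
emulate.

## Connectome model and thresholding

A connectome is a symmetric n×n matrix of mean fractional anisotropy
(FA) link weights over a fixed parcellation (default: 83
Desikan–Killiany-style regions — 68 cortical, 14 subcortical, brainstem;
the ventral diencephalon carries no node). Weights are dimensionless and
bounded in [0, 1]; reading rejects values outside that range unless
explicitly overridden, which catches streamline-count matrices passed by
mistake. Asymmetry up to a relative 1e-8 is averaged away (tractography
pipelines emit near-symmetric matrices); anything larger is an error.

Proportional thresholding keeps the m* = ⌊d·n(n−1)/2⌋ strongest links,
so the realised density never exceeds the target. Ties at the cut are
broken by ascending (row, column) index; the rule is arbitrary but
deterministic, so results are identical across platforms. Density and
mean weight are reported from the unthresholded network (density is
otherwise fixed by the threshold); every other metric is computed on the
binary graph at the configured density (default 25%).

## Metrics

*Clustering.* The global clustering coefficient is the unweighted mean
of the local coefficients over all nodes — not the transitivity ratio —
so the global and per-tier quantities are the same statistic evaluated
on different node sets.

*Normalised degree variance.* Population degree variance divided by the
maximum achievable over simple graphs with the same node and link
counts. The maximum is attained by one of two extremal families, the
quasi-complete graph (a clique assembled edge by edge) and the
quasi-star (hubs saturated one by one); the quasi-star on m links is the
complement of the quasi-complete graph on n(n−1)/2 − m links and
complementation preserves degree variance, so one construction serves
both. The construction is verified against exhaustive enumeration of
every labelled graph with n ≤ 7 in the test suite. Variances are
computed from exact integer sums so that equal degree multisets give
bit-identical values.

*Hierarchical complexity.* For each degree k shared by at least two
nodes of the evaluated set, each such node contributes its ascending
neighbour-degree sequence; R_k averages over the k sequence positions
the sample variance (denominator |C_k|−1) of the position values, and R
averages R_k over qualifying degrees (0 when none qualifies; k = 0
contributes nothing since there are no positions). When the evaluation
is restricted to a tier, degrees and neighbourhoods still come from the
full thresholded graph: tiers are node groupings, not induced subgraphs.
No further normalisation is applied; an optional switch divides degrees
by (n−1) before the variance for cross-size comparability. Reported
magnitudes therefore depend on n and density and are comparable within a
study, not across normalisation conventions.

## Tier assignment

Tier t ∈ {1..4} holds nodes with (1 − 0.25t)·k_max < k ≤
(1.25 − 0.25t)·k_max, i.e. upper bounds inclusive, lower bounds
exclusive, with k_max recomputed per subject. Isolated nodes satisfy
k = 0 ≤ 0.25·k_max and fall in Tier 4 (logged). Empty tiers are reported
as missing, never zero, and drop out of group statistics pairwise.

## Statistics

Rank-sum p-values are exact (full enumeration) when both groups have
≤ 10 observations and the pooled sample is tie-free; signed-rank
p-values are exact for ≤ 12 non-zero pairs with untied |differences|;
otherwise both use the tie-corrected, continuity-corrected normal
approximation. The thresholds trade enumeration cost against accuracy;
all alternatives are two-sided. Cohen's d uses the pooled
(n1 + n2 − 2)-denominator SD. Benjamini–Hochberg is the plain step-up
procedure; in the group-comparison analysis one family spans all global
and tier metrics jointly, while the tier-placement correlations are
descriptive and stay outside the family. The bootstrap correlation
interval is the 2.5/97.5 percentile interval over seeded paired
resamples (percentile rather than BCa: the simplest defensible choice);
degenerate resamples with a constant vector are skipped and logged.

## Lesion accounting and voxel mapping

Lesion loads are pure voxel-count ratios (WMH% = overlap × 100 / region
size), so voxel volumes cancel; absolute ml volumes use the affine's
voxel volume. Grids must match exactly — no resampling is performed,
since resampling belongs to the upstream registration stage. Mapped
"control tiers" arriving as probability maps are discretised by argmax
over background plus the four tier maps, ties to the lower label. The
not-assigned region label (5) is carried through all accounting.

The voxel stack crops to the bounding box of the ICV mask (half-open,
0-based ranges). Voxels constant across subjects carry no information:
they are excluded from testing and from the FDR family, and their B
coefficient is fixed at 0. The FDR family is all non-constant in-box
voxels. Because lesion columns are binary, all voxels with the same
per-group lesion counts share a p-value, and each distinct count pattern
is tested once through the ordinary test functions — an exact
memoisation, not an approximation. Continuous indicators are
dichotomised at the sample median (boundary values to the lower group);
quartile splits use linear-interpolation quantiles.

## SVR-by-SGD

The association model per outcome is a linear ε-insensitive support
vector regression with ridge penalty: minimise
mean_i max(0, |y_i − x_iᵀw − b| − ε) + (λ/2)‖w‖², intercept unpenalised,
λ = 1/47 by default and ε = IQR(outcome)/13.49 when set to "auto".
Voxel predictors stay raw 0/1 so B is in outcome units per lesion
presence; age and sex are standardised and penalised like any other
predictor (an alternative would pre-residualise the outcome; the chosen
convention keeps covariate adjustment inside the one convex objective).

The optimiser is per-sample subgradient SGD with the strongly-convex
decaying schedule η_t = 1/(λ(t + t₀)) (first step 0.1) and tail
averaging over the final half of the steps; averaging removes the
stochastic oscillation around the optimum so the suboptimality decays
like 1/T. On 20×30 instances, 60 000 epochs land within ~4e-5 of a
generic convex-optimiser solution of the same objective; production
voxel fits use 300 epochs, which is ample for stable B rankings.
Epoch order is drawn from a seeded generator, making every fit a pure
function of (inputs, seed). The objective of the averaged iterate is
recorded at ~40 checkpoints; convergence is declared when the per-epoch
relative change drops below 1e-6. The inner loop is numba-compiled.

## Synthetic cohorts

*Connectomes.* Subject graphs are drawn around a shared template: node
propensities u_i ∝ rank^(−0.25) (degree heterogeneity) combined with
latent 3-D positions, link probability ∝ u_i·u_j·exp(−dist/0.25),
rescaled per subject to its target density. The spatial factor
concentrates links locally and is what gives the graphs excess
clustering beyond their degree sequence — necessary for the rewiring
contrast to be detectable, and a structural feature real connectomes
share. FA weights are the subject's mean weight plus a small
score-coupled bonus (so strong links concentrate on hubs and the
thresholded graph keeps a hub core) plus N(0, 0.03) noise, clipped to
[0.01, 0.99]. Between-subject jitter of density (SD 0.025) and mean
weight (SD 0.015) matches the dispersion reported for cohorts of this
kind; at the default contrasts this puts group effect sizes near d ≈ 1–1.5,
the regime the analysis is meant to operate in. The patient-like group
receives its extra link probability preferentially on low-propensity
pairs (solved by bisection so the *expected realised* density gain
equals the requested delta), a constant mean-weight offset, and
degree-preserving double-edge swaps on 10% of links. Ground truth
records which metrics were planted.

*Lesions.* The head is an ellipsoidal ICV with a grey-matter shell and a
central ventricle ellipsoid; lesion probability is baseline 0.15 at the
ventricle wall decaying with length 4 voxels, restricted to white
matter — a periventricular field. One spherical cluster (radius 3, in
the right-anterior white matter) has its lesion log-odds shifted by
effect × indicator-z per subject (default 1.5 per SD). Masks are
Bernoulli samples followed by morphological closing for contiguity
(isolated salt-and-pepper voxels make rank tests uninformative). Age,
sex and a null indicator are drawn alongside. Tier label volumes for the
load analysis are concentric shells (native: per-subject jittered
boundaries; mapped: the shared template), which exercises the
native-vs-mapped comparison but does not reproduce anatomical tier
geometry.

*What passing tests show.* The simulations validate statistical
calibration, power at planted effect sizes, and recovery behaviour of
the chain. They do not establish anything about tractography quality,
registration accuracy, WMH segmentation, or the anatomical placement of
tiers in real cohorts — those stages are consumed, not modelled, and the
generators make no claim to biophysical realism.

## Problem sizes

Simulation-based checks run at the study scale the pipeline targets:
47 + 47 subjects × 83 nodes for the group comparison (100 replicates for
power, ~500 metric tests for calibration), 48³ voxel grids × 47 subjects
for lesion mapping (50 seeded SVR runs for recovery, 15 permutation
fits for the null), 500 replicates for bootstrap coverage, and
exhaustive enumeration up to n = 7 (all 2²¹ labelled 7-node graphs) for
the degree-variance extremals.

## Known limitations

- Hierarchical complexity and normalised degree variance magnitudes are
  convention-dependent (see above); only within-convention comparisons
  are meaningful.
- The exact/asymptotic switch points for the rank tests are pragmatic;
  near the switch the p-value changes discontinuously by design.
- The voxel-wise FDR treats voxels as exchangeable test units; spatial
  correlation of lesions makes the family smaller than nominal, so the
  procedure is conservative in the usual way of voxel-wise FDR. No
  cluster-extent or smoothing-based inference is provided.
- `fit_svr_sgd` at production epoch counts optimises to ranking
  stability, not to the certificate-grade tolerance used in the oracle
  comparison; raise `n_epochs` when absolute B values matter.
- The double-edge-swap rewiring attempts up to 50× the requested swaps
  and may fall short on very dense graphs (the realised count is not
  checked); at the default densities this has no practical effect.
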