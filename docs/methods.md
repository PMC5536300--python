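# Methods

## The analysis model

The pipeline treats a subject's resting-state BOLD data as a T×M matrix
(T time points, M in-mask voxels) generated by a small number of spatially
fixed networks with fluctuating time courses. Spatial ICA is run per
subject — never at the group level — so each participant's components keep
their individual spatial specificity; the cost is that components are not
in correspondence across subjects or across model orders, which is exactly
the problem hierarchical partner matching solves.

**Bidirectional (partner) matching.** For component i of set A, find its
best Tanimoto match j in set B; if i is also j's best match in A, the pair
is partnered. Tanimoto similarity is computed on maps clipped to
nonnegative z (default "continuous" mode); a binary mode (z ≥ 2.0,
intersection-over-union) is retained for sensitivity analysis. Clipping
avoids an arbitrary binarization threshold while keeping the index in
[0, 1] with value 1 only for identical maps.

**Clusters.** The match relation is only pairwise; clusters across > 2
subjects are its minimal transitive extension — connected components of
the pairwise match graph — kept when they span ≥ 50% of subjects, with at
most one component per subject (the member with the highest mean
similarity to the other subjects' members wins, so no subject is counted
twice in the one-sample t map). Stage 2 applies the same bidirectional
matching to cluster t-maps across model orders and keeps order-spanning
groups with Cronbach's alpha ≥ 0.7 (the conventional reliability bar;
alpha treats member maps as items and voxels as observations). Each
reproducible cluster carries per-subject representative maps (mean of the
subject's member components pooled across orders) and a final t-map
recomputed from those representatives.

**Effective connectivity.** The causal index of x on y at order p is the
Geweke-style log variance ratio of nested lag regressions; it is
nonnegative by construction and scale-invariant. The mediated index of x
on y through m is the *conditioning drop* max(0, GCI − GCI|m): large when
x's influence on y travels through m, near zero when the influence is
direct. An alternative path-product reading (the weaker leg of x→m→y) is
available as `gci_via_path_product`. One subtlety is intrinsic to lagged
chains: if x→m and m→y each act at one lag, x's influence reaches y only
after two steps, so a mediated index at order p = 1 is identically zero;
order-2 models (or BIC selection with max_p ≥ 2) are required to expose
one-lag chains. The shared VAR order for a cohort is chosen by BIC (joint
model over the cluster time courses, common effective sample, ties to the
smaller order) so indices are comparable across edges.

**Group inference.** Per-cluster voxelwise OLS on the subject
representatives with group (+1 patient / −1 control), mean-centered age
and sex; the group-contrast t reduces exactly to the pooled two-sample t
when no covariates are present. Multiple comparisons combine an
uncorrected two-sided voxel threshold (p = 0.01) with a cluster-extent
threshold returned by Monte-Carlo simulation: smooth Gaussian null maps on
the mask (white noise convolved to the residual smoothness, z-scored),
thresholded, 26-connected cluster sizes recorded, and the ceiling of the
95th percentile of the per-iteration maxima taken as the extent. Residual
smoothness is estimated from the lag-1 spatial autocorrelation of the
model residuals per axis (r₁ = exp(−d²/4σ²) for Gaussian-smoothed noise)
and combined as a geometric mean.

**Classification.** Features are per-subject scalars: mean representative
z over each significant cluster's surviving voxels, and the significant
edges' causal indices. The Gaussian kernel width 0.5 is read as the
length-scale on standardized features, K(u,v) = exp(−‖u−v‖²/(2·0.5²)); a
gamma-style reading is one config switch away. Standardization and
median imputation are computed inside each training fold; a
leave-one-out scheme, a stratified seeded 5-fold scheme, and
maximum-uncertainty LDA are provided. MLDA regularizes the pooled
within-class covariance by raising eigenvalues below the eigenvalue mean
up to the mean, which keeps the discriminant defined when features
outnumber subjects; feature contributions are |w|, normalized by the
largest coefficient. The repeated leave-one-out scheme (default 1000
trials) varies only genuinely stochastic elements (imputation jitter);
with complete data all trials coincide and the reported sd is 0.

## The synthetic cohort

The generator emulates a two-group resting-state study: 146 volumes at
TR 2.2 s per subject on a 16×16×12 grid of 3.75×3.75×3.5 mm voxels — a
desk-scale stand-in for a 64×64×34 acquisition over a 24 cm field of view
that preserves the smoothness-to-voxel-size ratios. Data are
Σₖ ampₖ·mapₖ(subject)·tcₖ(t) + iid Gaussian noise. Defaults, chosen once:

| parameter | default | why |
| --- | --- | --- |
| sources K | 4 | enough for a direct edge, a mediated chain and a bystander |
| source FWHM | 12 mm | network-scale blobs, several voxels wide |
| subject jitter | 1 mm | residual inter-subject misalignment after normalization |
| noise sd | 1.5 | see below |
| VAR self-lags | 0.3 | weakly persistent resting fluctuations |
| planted edges | 2→0, 0→3 at 0.5 (patients 0.25) | chain 2→0→3 mediated by source 0, no direct 2→3 link |
| amplitudes (patients) | ×0.7 on sources 0 and 2, ×1.3 on source 1 | weakened and strengthened networks coexist |
| subject amplitude jitter | lognormal(0, 0.25) | inter-subject variability; the severity correlate |
| severity | r = −0.30 to source 0's realized amplitude, patients only, standardized | a weak clinical correlate of the weakened network |
| outlier rate | 0.03 | occasional motion-corrupted volumes (1–3 mm jumps + global spikes) |
| ages | uniform 8–49 y, both groups | wide developmental range, group-matched |

The companion-matrix spectral radius of every accepted VAR spec must be
below 1 (stationarity), asserted at construction.

**Why noise sd 1.5.** Component maps are z-scored over voxels, so a pure
amplitude scale cancels exactly; group amplitude effects survive only
through the estimation error of the maps, whose size relative to the
source's spatial variance sets the sensitivity. At noise 1.5 the toy
cohort sits in the regime where the ×0.7 reduction produces clear negative
clusters while recovery correlations stay near 0.96 (comfortably above the
0.8 matching floor). This also explains an asymmetry the test-bench makes
explicit: the z-map value at source voxels saturates from below as
amplitude grows, so the ×1.3 increase yields roughly half the effect size
of the ×0.7 decrease — reliably positive in direction at 20+20 subjects,
but usually below the p<0.01 + extent bar. The recovery tests therefore
assert surviving negative clusters (Dice > 0.3 with the planted support)
for the weakened sources and a positive peak t at the strengthened
source's support. A second interaction worth knowing: halving an edge
coefficient lowers the *target* source's time-course variance, which acts
like an amplitude reduction on the target; the default wiring gives the
amplitude-strengthened source no planted inputs so the two effect families
do not cancel.

**What the generator does not emulate.** No physiological (cardiac or
respiratory) noise structure, no scanner drift, no EPI distortion or
slice-timing offsets, no spatial heterogeneity of noise, and severity is a
standardized score rather than any instrument's scale. Passing tests
demonstrate that the pipeline recovers the planted statistical structure
under these idealized conditions; they do not certify performance against
structured physiological artifacts or registration failure.

## Numerical choices

- Preprocessing outlier thresholds: motion derivative 0.5 mm
  (translations only by default; rotations can be folded in as arc
  displacement at a 65 mm radius) and global-signal |z| 3.0. Volume 0 has
  motion derivative 0 by convention. These are conventional
  artifact-repair settings; the planted-outlier recall test (≥ 0.9 over 20
  seeds) pins their behaviour.
- Smoothing uses a truncated (3 sd) separable Gaussian with the kernel
  renormalized over its in-grid support, which preserves each volume's
  total mass exactly; the stated sd is fwhm/√(8 ln 2) per axis in mm
  converted to voxel units.
- ICA: log-cosh contrast, iteration cap 500, tolerance 1e-5, seeded
  initial unmixing; component sign fixed so map skewness is nonnegative
  (matching and one-sample t tests need a convention). Convergence
  failures are flagged, not fatal.
- Degenerate one-sample t voxels: zero variance with zero mean gives t=0;
  zero variance with nonzero mean returns a cap (1e6) with a flag.
- Cluster connectivity is 26-neighbour in 3D, matching common fMRI
  cluster software.
- Rank-sum p-values use exact enumeration for tie-free samples up to 25
  per group, otherwise the normal approximation with tie correction; the
  z statistic (positive when the first-named group is larger) is always
  the normal-approximation value.
- Desk-scale runs enumerate model orders 10–40 in steps of 10; the
  full-scale default (20–130) is kept in the pipeline config. Problem
  sizes used by the test-bench — 20+20 subjects, 3072 voxels, 4 orders,
  200-replicate calibration loops on a 12×12×10 grid — were chosen so a
  complete run is a coffee-break job on one CPU.

## Known limitations

- The z-scored-map convention makes upward amplitude effects intrinsically
  harder to detect than downward ones (ceiling effect described above).
- Feature selection for classification follows the single-pass design
  (clusters/edges chosen on the full sample before CV), which is
  optimistic relative to nested selection; the accuracies reported on the
  toy cohort are validated against a permuted-label baseline instead.
- Leave-one-out permutation baselines sit slightly below 0.5 (training
  folds are unbalanced against the held-out class); this conservative bias
  is inherent to LOO, not a defect of the implementation.
- No frequency-domain or time-varying causality; no nonparametric
  permutation alternative to the Monte-Carlo extent threshold.
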