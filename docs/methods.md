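# Methods

This note documents the models, estimators, defaults, and numerical choices
of the package, and what the synthetic-data experiments do and do not show.

## Signal model of the synthetic cohort

Latent "neural" signals for N regions are drawn i.i.d. over time from a
block-structured covariance: 1 on the diagonal, `within_module_corr` (default
0.5) inside each planted module, `between_module_corr` (default 0) elsewhere.
The covariance is Cholesky-factorized once per configuration; a
non-positive-definite combination raises before any sampling.

**Resting runs** are latent draws plus stationary AR(1) noise (lag
coefficient 0.3, marginal SD 0.2) and per-node cosine drift with periods of
250–1000 s (amplitude 0.2) — slow enough to fall outside both the 0.01–0.1 Hz
resting band and the 200 s task high-pass. Two runs of 1200 volumes at
TR = 0.72 s are concatenated, emulating the concatenation of opposing
phase-encoding runs. With these defaults the sample correlation of a
within-module pair is attenuated from 0.5 to ≈ 0.47 by the noise and drift
variance, which the generator tests account for.

**Task sessions** (two sessions of 176 volumes) superimpose on the latent
draws: (a) per-module activation — amplitude × emotion-condition boxcar added
to every node of the module; (b) planted interactions — for each directed
edge (s → t, condition c, effect γ), the target gains γ · latent_s ·
boxcar_c *before* HRF convolution, which is exactly the quantity a gPPI
regression with deconvolution estimates. The summed neural signal is
convolved with a unit-sum canonical HRF, then observed with AR(1) noise,
drift, and six motion-like regressors (smooth random walks, SD 0.5) leaking
into the data through small random loadings (SD 0.1). The motion table is
emitted alongside the series.

The task design alternates 21 s emotion/shape blocks (3 s cue + six 2 s
trials with 1 s gaps), three blocks per condition per session. Six 21 s
blocks fill 126 s of the 126.72 s session, so the default inter-block
fixation is 0 s; a nonzero `fix_s` is supported and raises a clear error
naming the overrun when the sequence no longer fits the session.

**Planted effect size.** The emulated study reports no interaction effect
sizes, so γ is a calibration choice of this package: the default (1.5, sign
alternating across planted edges) puts the group-level t of a planted edge
at ≈ 15 with 50 subjects, comfortably above the Bonferroni detection
threshold (≈ 5.1 at 60 nodes), while leaving the global null untouched.
Planted edges use disjoint endpoints so their effects cannot interfere.

What the generator does **not** emulate: voxel-level structure, physiological
(cardiac/respiratory) noise, multiband artifacts, realistic motion spikes,
or hemodynamic variability across regions. Passing recovery tests therefore
demonstrate the correctness and calibration of the estimators under the
stated model, not robustness to every property of real BOLD data.

## Temporal preprocessing

All filters are projections onto per-run cosine bases, so linearity and
run-boundary separation are exact algebraic identities. The band-pass keeps
components with frequencies in [low, high] of the demeaned run; the
high-pass residualizes against mean, linear trend, and the
⌊2·T·TR/cutoff⌋ slowest cosines. Prewhitening is single-pass
Cochrane–Orcutt: an initial OLS fit, lag-1 residual autocorrelation ρ
(estimated within runs), then quasi-differencing of data and design with the
first row of each run dropped. ρ is per-column by default; the cohort gPPI
runner pools ρ across nodes within a session (their estimates are nearly
identical under the generator, and a pooled ρ lets all seed designs share
one whitening transform so the per-subject fit can be batched).

## Intrinsic networks

Partial correlations come from the analytic Ledoit–Wolf shrinkage estimator
(scikit-learn) unless a shrinkage intensity is forced; values are Fisher
z-transformed. Proportional thresholding keeps the ⌊cost·N(N−1)/2⌋ largest
*signed* upper-triangle values — the map-equation detector needs
non-negative weights, and cost-thresholding of z-matrices conventionally
retains the strongest positive couplings; negative survivors are zeroed with
a warning. Ties at the cutoff break by (weight desc, node pair lexicographic),
so the edge set is identical across platforms.

The community detector is a self-contained two-level map equation with a
Louvain-style optimizer (randomized single-node moves plus module
aggregation), seeded and deterministic; python-igraph's Infomap is used in
the test suite as an independent cross-check, never as the implementation.
Consensus clustering runs the detector `subject_runs` times per thresholded
subject matrix, averages co-assignment frequencies across subjects,
re-thresholds, runs `group_runs` more detections, and returns the modal
partition. A node is left unassigned when it is isolated after group
thresholding or when its aligned modal module appears in fewer than 50% of
group runs — the stability rule is this package's choice, exposed as a
parameter.

**Desk-scale thresholds.** The 0.035/0.07 costs are tied to a 273-node
graph (mean degree ≈ 9.5 / 19). What governs detectability is mean degree,
not the cost fraction, so the synthetic-cohort runners density-match: at 60
nodes the subject cost defaults to 0.16 and the group threshold to 0.33,
preserving those mean degrees. Full-scale costs remain the library-level
defaults of `consensus_cluster`.

## Task GLM and gPPI

Designs are built per session: HRF-convolved condition boxcars (cue merged
into its block by default; `separate` and `ignore` are options), unconvolved
motion regressors and their first differences, and a constant. The canonical
HRF is a double-gamma difference with modes exactly at 6 s (response) and
16 s (undershoot), ratio 6:1, 32 s support, unit peak.

Deconvolution estimates the latent series behind a seed's BOLD by ridge
regression on an orthonormal cosine representation, `min ‖HBc − y‖² +
λ‖c‖²`; the linear operator is precomputed per (T, TR, HRF, λ). The default
λ = 1 keeps the reconvolution R² of noiseless convolved designs above 0.99
while damping the high-frequency blow-up of the near-singular convolution
operator; deconvolution can be disabled, in which case the interaction term
is formed directly from the BOLD seed.

Per seed and session the gPPI design is: one interaction column per
condition (HRF ⊛ (deconvolved adjusted seed × condition boxcar)), the seed
time course, the convolved condition regressors, the nuisance block, and a
constant. Seeds are adjusted for the effects of interest (fitted condition
effects + residuals) before entering. All targets are fit at once; the
cohort runner vectorizes the normal equations across seeds and is tested to
machine precision against the explicit per-seed design path.

The difference matrix applies a two-sided one-sample t-test across subjects
to the session-averaged emotion-minus-shape interaction contrast of every
ordered pair, thresholded at α/(N(N−1)), signing significant means. The two
directions of a pair are estimated independently and may disagree.

## Permutation statistics

The rewiring null randomizes each sign's edge set by double-edge swaps
(target: 10 successful swaps per edge), rejecting swaps that would create
self-loops, duplicate an existing edge of either sign, or overwrite an
occupied cell; per-node in/out degree within each sign is therefore
preserved exactly, by construction. All permutation p-values are add-one
corrected, (1 + #{null ≥ obs})/(1 + n_perm), reported for enrichment and
depletion separately; density cells are judged at (α/2)/(2K²) (two one-sided
tests inside the 2K²-test family). A significant within-module cell
contributes in+out (2) to that module's network degree by default
(`diagonal="once"` is available). The χ² uniformity test uses the uniform
expectation degree-sum/K with K−1 degrees of freedom.

For hub classification, betweenness has no in/out variant and is shared
between the two profiles; path length ranks ascending (short = central) and
nodes reaching (or reached by) under 5% of the graph take the worst rank
rather than NaN. The top-third cutoff is ⌊N/3⌋ with stable index
tie-breaking. k-means (k = 2, 10 restarts, seeded) runs on z-scored
profiles with path length negated; the cluster with higher mean
standardized degree is the hub cluster.

**Discreteness of the Jaccard permutation test.** The strict add-one p-value
of a discrete statistic is valid but super-uniform (ties carry mass ≈ 0.2 at
the tested set sizes). Calibration checks therefore use the classical
randomized-test variant — `randomized=True`, p = (#{null > obs} + U·(1 +
#{null = obs}))/(1 + n_perm) — which is exactly Uniform(0,1) under the null;
inference always uses the strict, conservative version.

## Calibration of the difference-matrix null

With no planted effects, the group t statistics are calibrated to their
nominal t₄₉ reference: across 30 null cohorts (106,200 statistics), observed
tail counts at |t| > 3…5 sat at or below expectation, and the per-subject
contrast values showed no excess kurtosis. At exact calibration the expected
fraction of 100 replicate cohorts with an all-zero difference matrix is
e^(−0.05) ≈ 0.951, with a binomial standard error of ≈ 0.022 — replicate
batches of 100 therefore fluctuate between roughly 0.91 and 0.99, and
observed values of 0.93–0.95 are consistent with nominal family-wise error
control. False edges in null replicates are scattered across module pairs
and signs with no systematic pattern.

## Problem sizes

The synthetic study conditions are 60 nodes in 6 equal modules and 50
subjects — large enough for the consensus and group tests to operate in
their intended regime while keeping full-cohort runs to seconds. Consensus
clustering uses 30 detector runs per subject and 100 group runs (scaled-down
analogues of the 1,000/5,000 optimization trials used at full scale, which
are read as independent trials and remain configurable). Permutation tests
default to 10,000 draws at the library level; cohort-level validation uses
100–2,000 draws as noted in the tests.

## Known limitations

* The map-equation optimizer is two-level only; hierarchical and overlapping
  structure are out of scope.
* Prewhitening is AR(1); higher-order serial dependence (e.g. from HRF
  smoothing) is only partially removed. Group-level inference does not
  depend on it, but within-subject t statistics would be optimistic.
* The deconvolution ridge parameter is global, not adapted per seed.
* Voxel-level analyses (activation maps, cluster statistics) are replaced by
  ROI-level tests throughout.
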