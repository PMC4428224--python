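# Methods

## Model and procedure

The pipeline treats a subject's resting-state data as a node-level
multivariate time series and its connectivity as the full signed Pearson
correlation matrix between node representative series. All inference happens
on module–module blocks of that matrix.

1. **Parcellation.** Nodes are spheres (default radius 5 mm, i.e. 10 mm
   diameter) at MNI coordinates. Module membership is winner-take-all over
   RSN z-statistic maps sampled at the node location, assigned only when the
   winning z exceeds `z_threshold` (default 3). Unassigned nodes are
   dropped, as are modules with fewer than `min_module_size = 2` nodes —
   the general form of discarding a single-node module, since a one-node
   module supports no within-module edges worth summarizing.
2. **Connectivity.** Voxel (or node) series are detrended by regressing out
   Legendre polynomials of degree ≤ 2 on time rescaled to [−1, 1], then
   standardized to zero mean and unit sample variance. A node's
   representative series is the first left singular vector of its
   time × voxel matrix. Connectomes stay unthresholded and signed.
3. **Block SVD summary.** For each block, the m × S edge-by-subject matrix
   is row-demeaned and decomposed; coordinates are σ₁v₁ (PC scores).
   Row-demeaning makes the all-ones vector a right null vector, so
   coordinates sum to zero by construction — asserted throughout the tests.
   The block's per-subject mean edge correlation is kept alongside as the
   sign context the SVD discards.
4. **Group comparison.** Cohen's d with the classical pooled-SD formula
   (no small-sample correction; the screen is stated in terms of the
   conventional medium-effect bound 0.5, which presumes the classical
   formula). Wilcoxon rank-sum p-values are two-sided, exact when the
   combined tie-free sample is ≤ 20 and normal-approximated with tie
   correction otherwise; they are reported uncorrected, and every output
   table says so in its header.
5. **Edgewise consistency.** Per-edge d values are computed vectorized over
   the subject stack; edges are stratified by the signs of the two
   group-mean matrices (positive in both / negative in both / mixed; mixed
   edges are excluded from both analyses). Within a block and sign class,
   the consistency metric is (N₁ − N₂)/(N₁ + N₂) over edges with
   |d| ≥ `d_threshold`, computed only when the retained fraction reaches
   `retention_threshold` (default 5%).
6. **MVPA.** Linear SVM, C = 1, stratified k-fold CV (default fourfold:
   3 subjects per group per fold at 12 + 12) with feature z-scoring fitted
   on each training fold. Accuracy pools held-out predictions. Weights and
   dimensional scores come from a full-data refit, giving one score per
   subject; held-out fold-wise scores are available by flag.
7. **Behavior.** Pearson correlations of every block coordinate with every
   behavior measure across all subjects pooled; |r| ≥ `r_threshold`
   (default 0.5) flags large associations, p-values again uncorrected.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `z_threshold` | 3 | winner-take-all assignment floor (z units) |
| `d_threshold` | 0.5 | medium standardized mean difference |
| `retention_threshold` | 0.05 | minimum suprathreshold edge fraction per block/class |
| `consistency_threshold` | 0.33 | ≥ 2:1 directional edge majority |
| `r_threshold` | 0.5 | large correlation screen |
| `n_folds` | 4 | CV folds (75% train / 25% test) |
| `poly_order` | 2 | Legendre detrending degree |
| `radius_mm` | 5 | node sphere radius |

## Numerical and design choices

- **SVD sign conventions.** The representative node series is aligned to
  correlate positively with the mean voxel series (fallback: sign of the
  largest-magnitude voxel loading, logged). Block coordinates are aligned to
  correlate positively with the per-subject block mean connectivity
  (fallback: positive first nonzero edge loading, logged). Both
  decompositions leave the sign free, and downstream direction labels
  depend on it, so the rules are fixed and logged rather than left to the
  LAPACK sign.
- **Direction labels.** With the alignment above, d > 0 always means group 1
  sits higher on the block's connectivity scale. Positive-sign blocks read
  `G1>G2` / `G2>G1`; negative-sign blocks name the group with the stronger
  negative connectivity (`G1->G2-` when d < 0).
- **Coordinate scale.** Right singular vectors carry the singular value
  (PC scores). The scale cancels in Cohen's d, rank sums, correlations and
  standardized SVM inputs; it is fixed only for reproducibility.
- **"Whitening".** Implemented as per-series variance normalization, to
  which Pearson correlation is invariant; an AR(1) temporal pre-whitening
  pass (`prewhiten_ar1`) exists for sensitivity analysis.
- **Tie-breaking.** Exact z-map ties resolve to the earlier module in
  canonical order and are logged; with continuous real maps ties are
  measure-zero.
- **Retention arithmetic.** The 5% rule compares an exact rational fraction
  (`Fraction(n_supra, n_eligible) >= 1/20`), avoiding float boundary
  artifacts at exactly 5%; the comparison is ≥ ("at least"). The
  denominator is the block's edge count *within the current sign class*,
  because the positive- and negative-edge analyses are run separately.
- **Exact vs. approximate rank sum.** The exact/asymptotic switch sits at a
  combined n of 20, so a 12 + 12 study uses the (tie-corrected) normal
  approximation, matching common practice at that size; exact mode is a
  flag.
- **PSD repair.** Planted-effect target correlation matrices can leave the
  PSD cone; eigenvalues are clipped at zero, the matrix rescaled to unit
  diagonal, and the repair rejected if any entry moves by more than 0.01
  (configurable). Every repair is logged.
- **Degenerate inputs** raise with the offending unit named: constant
  series, all-zero voxel matrices, blocks without cross-subject variation,
  zero pooled SD, empty suprathreshold sets, spheres outside the image.

## The synthetic generator

The generator emulates the data regime of a small matched-group rsFC study:
two groups of 12 subjects, 9 canonical modules (reference node split
14/6/16/21/29/29/38/30/26 = 209 nodes), 200 timepoints per subject. Node
series are drawn from a multivariate normal whose correlation matrix is
block-constant: within-module correlation 0.45; between-module
correlations ±0.12 by default, positive within an early-sensory/DMN system
and a task-positive system and negative across them, so blocks with both
positive and negative means exist. Group effects are planted in the
*population* block correlation (delta added for the favored group), so the
modulewise effect size is governed by delta and the series length, not by
injected subject noise. Behavior measures are linear in a chosen block's
coordinates plus Gaussian noise; `noise_sd_for_target_r` sets the noise to
hit a target population correlation. A master seed spawns one child stream
per subject (keyed by subject index), so enlarging a group never changes
existing subjects' data.

What it deliberately does not model: hemodynamics, temporal autocorrelation
(available via an AR(1) option, default off), motion or physiological
artifacts, spatial smoothness, or heavy-tailed noise. Passing recovery
tests therefore demonstrates the analysis chain is correct and well-calibrated
under its own distributional assumptions — not that those assumptions hold
for any particular scanner or population.

## Problem sizes in the test suite

The Monte-Carlo suites (planted-block recovery over 50 seeds, MVPA over 20
seeds plus a 100-permutation null, behavior round trips over 100 seeds) run
on a 9-module system with 47 nodes (module split 4/3/4/5/6/6/8/6/5) rather
than the full 209: the statistical regime that matters for these checks —
12 + 12 subjects, T = 1000 (T = 200 for the behavior round trip), planted
delta = 0.3 — is unchanged, while each seed's cost drops by two orders of
magnitude. Structural checks (block counts, edge totals) use the full
209-node split. The behavior null-rate comparison simulates its own
|r| ≥ 0.5 reference rate from independent normal pairs at n = 24.

## Known limitations

- Pearson correlation conflates direct and indirect coupling; a
  partial-correlation backend is not provided.
- Blocks are summarized by the first singular pair only; a block whose
  group difference lives in a later component is invisible to the
  modulewise screen (the edgewise consistency screen partially covers this).
- No multiplicity correction anywhere, by design: outputs are exploratory
  effect-size screens and are labeled as such.
- The SVM uses a fixed C = 1 and no feature selection; accuracy estimates
  at n = 24 have large variance across fold assignments (the fold seed is
  explicit for this reason).
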