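# Methods

## Measurement model

A per-cell mean intensity for marker *i* in sample *p* is modeled as

    y_i^p = G_i^p (b_i^p + s_i^p)

where `G` is a multiplicative gain lumping every technical nuisance
(fixation, exposure, antibody lot, batch), `b > 0` the baseline /
autofluorescence level and `s ≥ 0` the true signal, zero for negative
cells. The working assumption throughout is a high signal-to-baseline
ratio (SBR = s/b̄): positive cells sit well above the background cloud.
All operations act on linear-scale intensities; any log transform is an
explicit caller choice, never implicit.

Normalization divides each (sample, marker) column by an estimate
`B̄ = G·b̄` of the gain-scaled baseline, read off cells known to be
negative for the marker. The gain cancels exactly:

    ȳ = y / B̄ = (b + s) / b̄

so normalized values are unitless, comparable across samples, and — with
the `max` background statistic — bounded by 1 for every truly negative
cell, which makes `ȳ > 1` a natural positivity gate. For two positive
cells from samples p and q the normalized ratio is
`(b̄ + s_q)/(b̄ + s_p)`, which converges to the true signal ratio
`s_q/s_p` as SBR grows; near the baseline the ratio is knowingly
compressed (no attempt is made to correct this low-SBR distortion).
Without normalization the same ratio converges to
`(G_q/G_p)(s_q/s_p)` — the biology scaled by an arbitrary technical
factor.

## Finding negative controls

**Exclusivity score.** Candidate mutually exclusive partners are ranked
by the singular-value ratio `r = σ₂/σ₁` of the uncentered n×2 matrix of
the two intensity columns. The columns are deliberately not centered or
standardized: the relevant geometry is an ellipse anchored at the origin
of intensity space, elongated (r → 0) for co-expressed markers and
near-circular (r → 1) for an L-shaped, mutually exclusive pattern.
Cells at zero in both columns are retained (they contribute to neither
singular direction but keep n honest). The score cannot distinguish a
true L shape from isotropic noise, so it is a ranking/QC statistic meant
to be cross-checked against biologically curated pairs; the pair
configuration file carries a `curated` / `data_driven` provenance flag
for exactly this reason.

**Two-group split.** For a (reference, target) pair within one sample,
the 2-D profiles decompose into up to three groups: reference-positive,
target-positive, double-negative. Because `s ≫ b > 0`, a profile from
one group cannot be written as a positive combination of profiles from
the other two (solving the 2×2 system for any sampled triple yields a
negative coefficient — this separability is exercised directly as a
property test), so self-expressive and low-rank models can recover the
partition.

The default backend is sparse subspace clustering:

* profiles are scaled to unit L2 norm. The clusters of interest are
  rays from the origin (expression directions, not magnitudes); without
  this step the L1 penalty — set relative to the largest inner product —
  makes high-magnitude cells everyone's preferred regressors and the
  dim double-negative cells lose their within-group connections.
  Normalization also makes the coefficients, and hence the labels,
  exactly invariant to rescaling the slice;
* each cell is regressed on all other cells with an L1 penalty
  (`λ = λ_rel · max_k |y_m·y_k|`, `λ_rel = 0.05` by default; the exact
  self-expression constraint is infeasible under noise, so the standard
  penalized relaxation is used). Self-coefficients are fixed at zero;
  coefficients are not sign-constrained, since on non-negative data the
  penalty does not select negative ones;
* the symmetrized coefficient magnitudes form an affinity, clustered by
  spectral clustering into **three** groups and merged down to two at
  the widest gap in mean reference intensity. A forced bipartition of a
  three-block affinity can shear the weakly connected double-negative
  block in half; clustering at the natural block count and merging
  recovers whichever of the two admissible splits
  ([ref-positive | rest] or [ref-positive + double-negative |
  target-positive]) the data supports. Both splits isolate a clean
  negative-control group.

SSC cost is quadratic in cell count; above `max_cells` (default 2000) a
seeded uniform subsample is clustered and remaining cells are assigned
to the nearest group centroid.

Alternative backends: rank-2 NNMF by multiplicative updates (random,
hence off-identity, initialization with seeded restarts to avoid the
trivial factorization of an n×2 matrix; labels from the widest gap in
the 1-D factor-dominance share, because a per-cell argmax scatters the
double-negative cells that load near-equally on both factors), and a
2-component full-covariance Gaussian mixture.

The group with the lower mean reference intensity is always labeled
reference-negative. If the two group means differ by less than a 1.2×
fold (configurable) the split carries no evidence of a positive
population and the marker/sample is skipped with a warning — a marker
with no positive cells is not useful and must not be normalized against
noise.

## Background inference and normalization

Per target, the background is the mean (default), max, or percentile
(default 99) of the reference intensities in the negative group. The
mean matches the expectation identities of the model; the max gives the
clean ≤ 1 bound but is outlier-sensitive; the 99th percentile is a
robust max. Multiple targets are combined by the median, so one
corrupted partner (non-specific staining making a pair positively
correlated) cannot drag the estimate. A background of exactly zero is
floored at half the smallest positive intensity of the column — division
must never occur by zero. Positive calls use a strict `ȳ > threshold`
(default 1): a cell exactly at background is not evidence of signal.

`global` mode pools all samples before splitting and applies one
background everywhere. It exists as the comparison arm: when samples
carry different gains, a pooled threshold mis-gates precisely the
samples whose gain deviates, and the divergence between local and global
results is itself a batch-effect diagnostic.

## Evaluation metrics

Adjacent sections are treated as near-technical replicates: any
sound thresholding or clustering should yield similar cell-type
composition across them. Metrics:

* Pearson correlation (Spearman optional) of per-sample composition
  fraction vectors — fractions, not counts, so section-area differences
  do not masquerade as discordance;
* coefficient of variation `c_v = σ/μ` of positive counts across a
  group's sections, with the sample standard deviation (ddof = 1 — a
  handful of sections is a sample, not a population);
* k-means (k-means++ with 10 restarts, seeded) on pooled all-marker
  profiles, run on raw and on normalized intensities; markers are
  z-scored on the pooled cells first so no single bright channel
  dominates the Euclidean metric. Per-sample cluster-membership
  compositions are correlated pairwise;
* a quantile-normalization baseline that affinely maps each sample's
  [P1, P99] intensity window onto the pooled window. It inherits QN's
  known failure mode — a sample genuinely lacking positives for a
  marker has its negatives stretched into the pooled positive range —
  which the test suite demonstrates against the background-normalization
  behavior.

In the gating-based reports the default background statistic is the 99th
percentile, not the mean: a gate must sit at the top of the negative
distribution, whereas the mean of a spread-out negative cloud would call
roughly half of the negatives positive.

## Synthetic data

Generators emit feature tables plus complete latent truth (b, s, gains,
labels), and are bit-deterministic given their config.

* Baselines are drawn per cell, lognormal by default with CV 0.2
  (fluorescence intensities are positive and right-skewed); gamma and
  truncated-gaussian alternatives exist for robustness checks, and
  `noise="none"` gives exact noise-free algebra (`y = G(b+s)` holds to
  the last bit). Signals are deterministic at `s = SBR · b̄`.
* The two-sample design (defaults: 2000 positive + 2000 negative cells
  per sample, gains (1, 0.5), SBR 100) is the gain-cancellation study:
  un-normalized cross-sample ratios converge to the gain ratio,
  normalized ratios to the true signal ratio, with the closed form
  `(b̄+s_q)/(b̄+s_p)` emitted alongside for oracle comparison on an
  (SBR × true-ratio) grid.
* The three-group fixture realizes the exclusive-pair geometry
  (group sizes 60/60/60 by default) and warns below SBR 5, where the
  `s ≫ b` separability premise degrades.
* The multi-section design emulates adjacent TMA sections: four cell
  types (tumor positive for a 3-marker cancer block; T cells CD45+CD8+;
  B cells CD45+CD20+; stromal all-negative — the immune subtypes give
  the composition vector genuine structure across markers), composition
  (0.40, 0.20, 0.15, 0.25) jittered per section by a Dirichlet-
  multinomial with concentration 200 (small, honest "almost
  replicates"), 1000 cells per section, and per-section gains (1, 2,
  0.5) applied to the cancer block only.

The batch-effect phenomenology tests run this design at SBR 4: the
local-vs-global contrast requires the motivating regime in which the
negative range of the high-gain section overlaps the positive range of
the low-gain section, i.e. `G_hi · b`-values exceeding
`G_lo · (b + s)`; with gains spanning 4× that means SBR below about 5.
At SBR 10 and these gains a pooled threshold still gates correctly and
the contrast between local and global inference is marginal.

What the simulations do **not** contain: spatial structure, segmentation
error, per-pixel background variation, marker-specific baseline
differences, cell-to-cell signal heterogeneity, or partially exclusive
("leaky") marker pairs. Passing tests therefore demonstrate the
correctness of the algorithms under the stated model, not performance on
real tissue; on real data the curated-pair QC step and the robust
(percentile/median) statistics carry the weight.

## Numerical choices and problem sizes

* Exclusivity ratios at or below 1e-12 of σ₁ are reported as exactly 0
  (rank-1 case); the ratio is clipped into [0, 1] against rounding.
* The self-expression lasso runs with tolerance 1e-3: cells on a shared
  ray are near-collinear regressors, where coordinate descent closes
  the last of the duality gap very slowly without changing which cells
  carry coefficient mass.
* The affinity receives a 1e-10 floor so isolated cells remain connected
  for the spectral embedding.
* Every stochastic step (subsampling, spectral k-means, NNMF restarts,
  GMM initialization, k-means evaluation) takes an explicit seed,
  default 0; CLI outputs embed a hash of the full parameter set.
* Test and acceptance problem sizes: 20 replicates of the two-sample
  study at 2000+2000 cells; grouping fixtures at 180 cells; background
  recovery at 120+120 cells; the sections study at 3×1000 cells with the
  SSC subsample cap at 400. These sizes give stable statistics for every
  asserted contrast while keeping the full suite around two minutes.

## Known limitations

* A marker whose sample truly lacks positive cells cannot be normalized
  (by design); it is skipped and logged, and passes through unnormalized
  unless strict mode is on.
* The background is one scalar per (sample, marker); spatially varying
  autofluorescence is out of scope.
* Low-SBR signal compression is inherent to division-by-background and
  is reported (ratio-distortion grid) but not corrected.
* The exclusivity score cannot by itself detect non-specific staining;
  a corrupted pair is mitigated by the median across several targets and
  by curated-pair cross-checks, not detected automatically.
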