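# Methods

This note records the models, estimators and numerical conventions
implemented in `radscreen`, the choices made where the underlying
methodology leaves the design open, and what the synthetic cohorts do and
do not emulate.

## Integral survival

The scalar phenotype is the trapezoidal area of the survival-fraction
curve over log2 dose, rescaled by 7/log2 10 so the standard panel
(1, 2, 3, 4, 5, 6, 8, 10 Gy; log2-dose range [0, log2 10]) maps to [0, 7].
Conventions:

* The printed form of the trapezoid summand is read as
  ½[f(X₁)+f(X₂)]·ΔX — the standard trapezoid rule — because the scale's
  anchors force it: all-ones survival must score 7 and all-zeros 0.
* Mock (0 Gy) wells are used only for normalisation, never as an
  integration node; the node list starts at 1 Gy.
* Survival fractions are clipped to [0, 1] before integration so the 0–7
  bound is an invariant (noisy wells can exceed mock); raw unclipped
  fractions are retained on the curve object for QC.
* For a non-standard dose panel the attainable maximum is
  7·(log2 dmax − log2 dmin)/log2 10; `max_attainable_score` reports it.
* Clonogenic AUC integrates on the **linear** dose axis (units Gy), the
  conventional choice when comparing with colony-formation curves; the
  log-axis alternative was considered and rejected as non-standard for
  that assay.
* "Linear range" density selection is not a published rule; the package
  uses a deterministic stand-in — the density whose mock-well signal is
  closest to a configurable instrument mid-range (default 10⁵ RLU), ties
  toward the lower density.

## Copy-number features

* fSCNA = Σ length(|log2 ratio| > 0.2) / Σ length over the segments
  present. The threshold applies to the amplitude (gains and losses), the
  inequality is strict, and the denominator is the measured-genome length,
  not a fixed genome size. All three choices follow the natural reading of
  "length of segments with values larger than 0.2 divided by the length of
  all segments measured"; counting gains only is a plausible alternative
  and is available by passing a one-sided threshold upstream.
* Gene-level copy number is the signed log2 ratio of the overlapping
  segment with maximum |log2 ratio| (signed, because the ±0.7 binarisation
  needs the sign). Ties break toward the segment with larger overlap, then
  the leftmost — a deterministic rule the source definition leaves open.
* Amplification/deletion calls are strict inequalities (> 0.7, < −0.7);
  a value of exactly ±0.7 is not called. Missing gene values binarise to 0
  and are counted.
* Coordinates are 0-based half-open internally; SEG files are 1-based
  inclusive on disk and converted on read/write. Chromosome labels are
  never normalised ("chr1" ≠ "1" deliberately, to surface input
  mismatches early).

## Information coefficient

IC = sign(ρ)·sqrt(1 − exp(−2Î)) maps a mutual-information estimate onto
[−1, 1] and reduces to |r| for bivariate Gaussians. ρ is the Pearson
correlation (point-biserial for 0/1 features) computed on
rank-inverse-normal (INT) transformed values. Estimator details:

* **Standardisation.** Phenotype and continuous features are INT
  transformed (average ties, Blom-style offsets) before density
  estimation. This makes the IC exactly invariant to monotone increasing
  phenotype transforms and stabilises bandwidth choice. The transform is
  computed through the mirrored lower-tail quantile so negating the input
  negates the output bitwise; combined with flipping the phenotype axis to
  the correlation sign before density estimation, antisymmetry under
  phenotype negation is exact, not approximate.
* **Densities.** Gaussian product kernels evaluated on a 100-point grid
  per continuous axis spanning the data ±3 bandwidths. The bandwidth is
  Silverman's rule of thumb (0.9·min(sd, IQR/1.349)·n^(−1/5)) times a
  multiplier (default 2.5), shrunk by (1 − 0.75|ρ|) for
  continuous–continuous pairs so strongly dependent pairs are not smoothed
  into independence — the classical adaptive refinement of this estimator
  family.
* **Bias handling (continuous path).** The plug-in grid estimate is
  positively biased in small samples: every observation contributes joint
  kernel mass at its own location, so even independent data yield Î > 0.
  The estimator subtracts its own independence baseline — the mean plug-in
  Î over 16 internally seeded permutations of the phenotype axis (same
  marginals, same bandwidths) — and clamps at 0. With the default
  multiplier this calibrates the estimator so that a perfectly dependent
  pair scores ≈ 0.95 while 100 independent n=200 pairs stay below |IC| ≈
  0.14 (the residual is dominated by sampling correlation itself, which no
  estimator that reduces to |r| can remove).
* **Binary features.** Î is computed from the two class-conditional
  phenotype densities and the class priors (a mixture KL identity), using
  a bandwidth from the full phenotype. No baseline subtraction: the
  permutation test compares observed and permuted values of the *same*
  statistic, so the bias cancels, and the whole batch — features and
  permutations alike — reduces to one (features × samples)(samples × grid)
  matrix product. A thousand-feature screen with 199 permutations per
  feature runs in about a second.
* **Preconditions.** ≥ 8 paired observations; binary features need ≥ 2
  carriers and ≥ 2 non-carriers (configurable); constant inputs are
  signalled, not silently scored.

**Permutation test.** p = (1 + #{permutations at least as extreme}) /
(n_perm + 1); the add-one correction keeps p ≥ 1/(n_perm+1) > 0. The
default is two-sided (|IC_perm| ≥ |IC_obs|), which is uniform under the
null. A directional variant (extremity in the direction of the observed
sign) is available but deliberately not the default: choosing the
direction after seeing the data makes that p uniform on (0, ½] under the
null, i.e. it rejects ~2α of true nulls at level α. Screens that need a
directional readout should fix the direction a priori via the ranking
flag, not the p-value.

No multiple-testing correction is applied by default (nominal empirical p
values are reported); Benjamini–Hochberg adjustment is available by flag.

## ssGSEA and signature scores

* Genes are ranked by decreasing expression (ties → average rank). Walking
  the ranked list, the in-set cumulative weight uses |rank|^α normalised
  over set members (α = 0.25 default, rank N for the top gene), the
  out-of-set ECDF is uniform, and the score is the *sum* of the ECDF
  differences (integrated, not maximum deviation). Scores therefore depend
  only on expression ranks — strictly increasing transforms leave them
  bitwise unchanged.
* The score of a random gene set over random data is exactly mean-zero for
  α = 0 (uniform weights), by exchangeability. For α > 0 the rank
  weighting introduces a small intrinsic *positive* offset (verified by
  exact enumeration over all k-subsets at small N); ssGSEA scores are
  therefore not centred and should be compared across samples or against
  permutation nulls, never against 0. No cross-sample normalisation is
  applied by default.
* Sets need ≥ 5 members present in the matrix (configurable) and a
  non-empty complement.
* Signature summary scores: per gene z = (x − median)/SD across samples
  (sample SD, n−1); per sample the mean z over signature genes; the
  per-sample means re-normalised to SDs-from-median across the cohort, so
  each signature's cohort median is exactly 0 and the result is invariant
  to gene-wise affine rescaling of the raw expression. Multiple signatures
  average their normalised scores. Zero-SD genes are excluded with a
  warning.

## Cohort statistics

D'Agostino–Pearson K² (transformed skewness and kurtosis Z statistics,
chi-square 2 df) is computed via `scipy.stats.normaltest`; the test suite
cross-checks it against an independent implementation of the printed
formulas. The test warns below n = 20 (its validity floor). The
`gaussian_flag` defaults to the screen's historical reporting convention —
K² < 0.65 **and** p > 0.5 — kept for fidelity but documented as a
convention, not a statistical criterion: even perfect normal samples
satisfy K² < 0.65 only ~28 % of the time (P(χ²₂ < 0.65) ≈ 0.28). Both
thresholds are parameters; the conventional "not rejected at α = 0.05"
rule is obtained with `k2_flag_max=inf, p_flag_min=0.05`. No correction is
applied across per-lineage tests. Distribution reports use
Freedman–Diaconis histogram bins (configurable), a Gaussian KDE on a
uniform grid, and Blom plotting positions for the normal Q–Q pairs.

## Synthetic cohorts

The generator produces complete cohorts — plates, segments, mutations,
expression, gene sets — with recoverable ground truth.

* **Survival.** True integral survival per lineage ~ Normal(mean, sd)
  truncated to [0, 7]. Carriers of each planted feature are shifted by
  effect_size × the cohort SD (the SD of the drawn truths before shifts),
  then all truths are clipped to [0, 7]; effects near the scale boundary
  therefore attenuate, and the recovery checks use mid-scale means.
* **Plates.** The dose–response inversion uses the monotone family
  A·exp(−b·x), x = log2(dose/dmin), A ∈ [0, 1]. A pure exponential is
  pinned to 1 at the lowest dose, so its trapezoid score cannot fall below
  half the first trapezoid (≈ 1.054 on the standard panel); below that
  regime the amplitude A scales a steep (b = 60) exponential, above it b
  is found by Brent root-solving (xtol 10⁻¹⁴). The recomputed score
  matches the target to < 10⁻⁶ by construction. Luminescence = density ×
  signal-per-cell (default 10³ RLU/cell at densities 25/75/225 cells per
  well) × survival fraction × multiplicative log-normal noise with mean 1
  and CV `noise_cv`. Defaults — the standard 8-dose panel, quadruplicate
  wells, three densities — mirror the real assay design; the plate noise
  magnitude is not published, and the default CV of 0.1 is a plausible
  testing level, not an estimate.
* **Segments.** Each chromosome of a toy genome (default 10 × 1 Mb, 200
  catalogued genes) is cut into random tiles; altered status is assigned
  to shuffled tiles until exactly round(target × genome) bases are
  altered, splitting one tile at the boundary, so the profile's fSCNA
  matches the per-line target to coordinate rounding. Altered tiles draw
  |log2 ratio| from U(0.3, 1.2) with random sign; neutral tiles from
  N(0, 0.05) clipped strictly inside the 0.2 threshold. Planted
  amplifications/deletions overwrite the target gene's interval (ratio ±1)
  in carrier profiles by splitting tiles at the gene boundaries; this
  perturbs fSCNA by at most one gene length.
* **Expression.** Gene baselines ~ U(4, 10) (log2-scale levels) with unit
  Gaussian noise; genes linked to a planted feature shift by effect_size
  per-gene SDs in carriers. Gene sets: one set per planted program plus
  five random background sets.
* **Nulls.** Null mutation features draw carriers independently of
  survival at prevalences U(0.1, 0.4) — associations to them are false
  positives by construction.
* **Seeding.** A single global seed expands into per-component child
  generators via fixed stream offsets (`default_rng([seed, offset])`);
  identical configurations are bitwise reproducible while components stay
  individually stable under changes elsewhere.

**What the generator does not emulate:** array-level artefacts and
segmentation noise (segments are exact tilings), lineage-specific
mutational signatures, correlated feature structure (nulls are mutually
independent), batch effects, cell-line identity errors, and
dose-dependent assay heteroscedasticity. Tests passing on these cohorts
validate the pipeline's correctness and calibration, not the biological
variability of real screens.

## Pipeline and reproducibility

Stages run in a fixed order (scoring → copy-number features → mutation
matrix → IC screens → expression correlation → ssGSEA/signatures → cohort
statistics). Every table carries a provenance header: package version,
seed and a hash of the analysis configuration (the output location is
excluded from the hash). A stage failure halts the run with a stage-named
error and leaves a FAILED marker beside the partial outputs. CLI exit
codes: 0 success, 2 usage/configuration, 3 data or format error, 4
statistical precondition.

## Problem sizes used in validation

The test suite validates at desk scale, chosen to keep the full run in
tens of seconds: oracle comparisons on 50–100 random curves/genomes;
IC calibration on 1,000 null features at n = 100 with 199 permutations;
planted-effect recovery (1.5 SD, 20 % prevalence, 1,000 features) over
100 seeded runs; ssGSEA null behaviour over 10⁴ random sets; end-to-end
bundles on 30–100-line cohorts. The real screen's headline correlations
depend on its 533-line dataset and the original IC estimator's exact
settings and are not reproduced numerically; the calibration and recovery
properties above are the package's validated claims.

## Known limitations

* The IC's absolute magnitude depends on the bandwidth settings; only
  comparisons under a fixed estimator configuration (and their permutation
  p values) are meaningful. Published IC values from other implementations
  will differ.
* Continuous–continuous permutation p values loop over permutations (no
  batched path yet); large n_perm on expression-vs-phenotype screens is
  the slowest corner of the package.
* `fold_range` is infinite when a lineage contains a fully sensitive line
  (minimum score 0).
* The mutation-matrix region restriction keys on the *first* residue of a
  protein change; range notations restrict by their start residue only.
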