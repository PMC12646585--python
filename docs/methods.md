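# Methods

This note records the statistical methods implemented in `tgxddi`, the
generative model behind the synthetic data, the default parameters and
their rationale, and the package's own interpretation choices where the
underlying assay description leaves room.

## 1. The TGx-DDI paradigm

The TGx-DDI biomarker is a 64-gene transcriptomic signature measured in
human TK6 lymphoblastoid cells after chemical exposure. A classifier
trained on reference agents of known DNA-damage-inducing (DDI) or non-DDI
mode of action is applied to each exposed sample's log2 expression ratios
(treated over concurrent solvent control). Three independent prongs each
produce a call, and the prongs are combined conservatively.

### 1.1 Probability analysis (PA)

A nearest shrunken centroid (PAM-style) classifier in its canonical form:

* per-class centroids `c_k`, overall centroid `c`, pooled within-class
  standard deviation `s_i` with denominator `n - K`;
* fudge factor `s0 = median(s_i)` guarding against near-zero variances;
* t-like statistics `d_ik = (c_ki - c_i) / (m_k (s_i + s0))` with
  `m_k = sqrt(1/n_k - 1/n)`, soft-thresholded by the shrinkage `Δ`
  (default 0: no gene selection, all 64 genes contribute);
* discriminant `δ_k(x) = Σ_i (x_i - c'_ki)^2 / (s_i + s0)^2 - 2 log π_k`
  and posterior `softmax(-δ/2)`.

A sample is called DDI when `P(DDI | x) >= 0.9`, non-DDI when
`P(nonDDI | x) >= 0.9`, otherwise inconclusive. With `Δ = 0` the centroids
equal the plain class means; this is verified in the tests against both a
hand-written loop and scikit-learn's `NearestCentroid`.

### 1.2 Principal component analysis (PCA)

The training profiles are centered and decomposed by SVD. Test samples are
projected onto PC1, oriented so the DDI training mean is positive. The
midpoint of the two class means on PC1 defines the decision boundary; an
**inconclusive band** of half-width `band_fraction x |gap|` (default
`band_fraction = 0.1`, i.e. 10% of the distance between the class means)
is centered on the midpoint. Scores strictly outside the band are
conclusive; scores on or inside the band (boundary included) are
inconclusive — the band exists to absorb borderline projections, so the
boundary itself is treated as borderline.

### 1.3 Hierarchical clustering analysis (HCA)

For each test sample, the 28 training profiles plus that one sample are
clustered (euclidean distance, average linkage by default) and the
dendrogram is cut into two branches. The call is the strict majority label
of the training members sharing the test sample's branch
(`purity_threshold = 0.5`); a branch containing only the test sample, or a
branch without a strict majority, yields inconclusive. Clustering one test
sample at a time keeps each call independent of the rest of the batch.

### 1.4 Combination and hierarchy

Per sample: DDI if **any** prong says DDI; non-DDI only if **all three**
say non-DDI; otherwise the majority of {non-DDI, inconclusive}. This is
monotone: upgrading any prong toward DDI never moves the combined call
away from DDI (property-tested exhaustively over all 27 combinations).

Sample calls roll up to a concentration call by plurality over replicates
(>= 2 required), with ties broken toward the more hazard-conservative call
(DDI > inconclusive > non-DDI). Chemical calls per (lab, compound): DDI if
any retained concentration is DDI; non-DDI only when the test is *valid*
and the plurality of retained concentration calls is non-DDI; otherwise
inconclusive.

### 1.5 Cytotoxicity rules

From the MTT assay (`viability = 100 (A_treated - A_blank) /
(A_control - A_blank)`, clipped to [0, 100]):

* a concentration with viability **strictly below 40%** shows overt
  cytotoxicity and is excluded from calling;
* a test is **valid** (can support a negative call) iff the top
  concentration's viability lies in the **closed** interval [40%, 50%]
  (the 55 +/- 5% cytotoxicity target) **or** the top concentration is at
  least the 1 mM limit concentration (inclusive: "reached the limit").

Positive DDI calls are never gated by validity — the paradigm is
deliberately asymmetric toward hazard detection.

## 2. Performance and concordance statistics

* **Confusion tables** have assay call as rows and the truth standard as
  columns; inconclusive calls are tallied separately and excluded from the
  2x2 by default (optionally counted as errors).
* **Exact binomial CIs** are Clopper-Pearson via beta quantiles
  (`lower = B(α/2; x, n-x+1)`, `upper = B(1-α/2; x+1, n-x)`), with the
  boundary conventions lower = 0 at x = 0 and upper = 1 at x = n. The
  display convention rounds proportions half-up to whole percents.
  The tests verify the quantile form against direct bisection of the
  binomial tails for every x at every n <= 60.
* **Within-lab concordance**: one test = one (lab, compound) pair; it is
  concordant iff within every concentration the replicate calls are
  identical.
* **Cross-site agreement** over compounds conclusively called by both labs
  of a pair: Cohen's kappa (`Pe` from the marginals), PABAK (`2 Po - 1`
  for two categories), and Gwet's AC1 (`Pe = 2π(1-π)`, `π` the mean of
  the two labs' DDI marginals; robust at extreme prevalence, where kappa
  collapses). Interpretation bands: poor < 0.2 <= fair < 0.41 <=
  moderate < 0.61 <= good < 0.81 <= very good. The printed band scale has
  micro-gaps (e.g. 0.41-0.6 vs 0.61-0.8); each printed lower bound is
  inclusive and values inside a gap map to the band below.
* **Reference-RNA reproducibility**: counts scaled to each lab's total,
  log2 with a 0.5 pseudocount, pairwise Pearson and Spearman.
* A coefficient that is mathematically undefined for a pair (both labs
  constant) is reported as NaN / "undefined" in tabular output; the scalar
  functions raise.

## 3. Synthetic data model

The generator's defaults encode the ring-trial design itself: 4 labs, 14
blinded test compounds (6 DDI, 8 non-DDI, 3 requiring metabolic
activation), 3 concentrations, 3 replicates, 3 solvent controls and one
shared reference RNA per lab, plus assay controls (a positive clastogen, a
negative compound, and an activation-dependent positive).

* **Counts** are negative binomial via gamma-Poisson mixing
  (`var = μ + d μ^2`, dispersion `d = 0.05`), with log-normal gene
  baselines (median ≈ 600 counts) and multiplicative lab effects
  (log-SD 0.1).
* **Signal**: a DDI exposure multiplies the responsive biomarker genes by
  `2^(effect x rank/3)` at concentration rank 1-3; per-agent effects are
  drawn from `N(ddi_effect_mean = 2.0, sd = 0.5)` for DDI agents and
  `N(0, 0.25)` for non-DDI agents. `fraction_responsive = 0.75` of the 64
  panel genes respond. These defaults give class separation comparable to
  a strong genotoxic stress response while leaving QC and replicate noise
  realistic.
* **Viability** follows deterministic Hill curves per compound
  (`hill = 2`, floor 5%), parameterized so the top concentration lands in
  the 40-50% validity window (75% for >= 1 mM limit compounds, which are
  valid by concentration instead).
* **QC metrics** (FOV, binding density, RIN) are drawn in realistic clean
  ranges; positive-control linearity is computed from the simulated spike
  counts, so occasional samples genuinely fail R^2 >= 0.95 through Poisson
  noise on the faintest (0.125 fM) spike — mirroring the handful of
  replicates lost to QC in a real trial.

What the generator does **not** attempt: probe-level sequence biases,
batch drift within a lab (each lab is one batch), RNA degradation,
cross-hybridization, or dose-dependent transcriptional remodeling beyond
the single multiplicative signature.

## 4. Numerical and interpretation choices

* Pseudocount 0.5 before any log or geometric mean; normalization factors
  are cohort geometric means per (lab, batch), applied in two steps
  (positive controls, then housekeeping genes).
* One integer seed drives everything; per-stage seeds are derived from it
  through `numpy.random.default_rng` and kept below 2^31.
* PA threshold 0.9 is inclusive (a posterior of exactly 0.9 is
  conclusive); the PCA band boundary is inconclusive; the 40% exclusion
  threshold is strict; the 40-50% validity window and the 1 mM limit are
  inclusive. Boundary conventions follow the rule of thumb that
  thresholds *met* count as met, while the exclusion rule ("below 40%")
  is a strict inequality.
* A concentration whose retained replicate count falls below 2 after QC is
  treated as excluded (reason `QC`) rather than producing a call from a
  single replicate.
* The null-exposure control (`RunConfig.exposure_effect`) applies a
  zero-effect exposure model against a normally trained classifier. A
  classifier *trained* on zero effect would have a degenerate PC1 band and
  meaningless centroids, so the null is defined on the exposure side; the
  all-null case is characterized separately by its indifferent (≈ 0.5) PA
  posterior.

## 5. Limitations

* The synthetic generator is a study-design emulator, not a biological
  model; absolute effect sizes are calibrated for plausibility, not fit to
  any measured dataset.
* HCA branch purity uses a strict-majority rule; other operationalizations
  of "which branch the sample falls into" (e.g. cophenetic distance to
  class medoids) could call borderline samples differently.
* Performance statistics treat the truth standard as error-free.
* Agreement coefficients are computed per lab pair on small n (typically
  14 compounds); their CIs are not reported because exact small-sample
  intervals for kappa-type statistics are not standardized.
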