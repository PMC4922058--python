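# Methods

## Scope and model

`metaboclust` reproduces a complete multi-omics subtyping analysis of
breast-tumor HR-MAS MRS spectra: spectral preprocessing, Ward/Euclidean
hierarchical clustering into three metabolic clusters (Mc1–Mc3), PLS-DA
validation with permutation testing, fixed-window metabolite
quantification with rank-based cluster statistics, Fisher-exact subtype
association, SAM differential expression, signal-to-noise GSEA, and joint
gene+metabolite pathway over-representation.  Because the original cohort
is not publicly deposited, the package is driven by a synthetic-cohort
generator whose default parameters are the published per-cluster summary
tables (metabolite means/dispersions, subtype and clinical category
counts, cluster sizes 58/58/112).  The generator is first-class, tested
code: the claims the test suite makes are claims about this generative
model, not about any real cohort.

## The synthetic spectral model

A spectrum is a nonnegative intensity profile on a ppm grid
(default 1.20–5.00 ppm, step 0.0005, descending axis):

    S(x) = Σ_m s_m · L_m · T_m(x)  +  B(x)  +  lipids(x),
    observed = gain · (S + ε)

* **Metabolite templates** `T_m`: unit-area single resonances at literature
  chemical shifts.  The default lineshape is Gaussian with FWHM 0.003 ppm.
  A Lorentzian option exists, but Gaussian is the default because the
  quantified choline-region resonances (GPC 3.232, PCho 3.225, choline
  3.205 ppm) are only 0.007 ppm apart: Lorentzian tails at that spacing put
  ~8 % of each neighbour's area into the other's integration window, which
  destroys per-sample level recovery; Gaussian tails make the leak < 0.1 %.
* **Integration windows**: ±0.015 ppm around each resonance, narrowed where
  needed to keep all 18 windows pairwise disjoint and clear of the five
  lipid exclusion windows (GPC/PCho ±0.003, choline ±0.009, acetate ±0.009
  — its resonance at 1.92 ppm sits 0.01 ppm from the 1.93–2.09 exclusion).
  The resulting capture fraction (< 1) is absorbed by the calibration.
* **Levels** `L_m`: drawn per sample from a zero-truncated normal with the
  configured per-cluster mean and dispersion.  The dispersion column of the
  published table is printed as "SE" but interpreted as a per-cluster SD
  (flag `dispersion="se"` preserves the alternative, converting SE→SD by
  √n): read as SE it would imply SDs far above the means, impossible for a
  nonnegative quantity.  The truncated-normal *location* is moment-matched
  (Brent root of the inverse-Mills identity) so that the realized mean
  equals the configured mean — plain truncation would inflate
  scyllo-inositol's Mc2 mean by ~2×.  For high-dispersion metabolites the
  realized SD is necessarily below the printed value (a zero-truncated
  normal cannot exceed CV ≈ 1 at a fixed positive mean).
  An optional per-sample common factor (`level_corr`) induces within-cluster
  level correlation while preserving the marginals; the default is 0
  (independent levels).
* **Background** `B`: a flat plateau over every retained grid point outside
  all integration windows, with per-sample amplitude chosen so the
  retained-point mean of the noiseless spectrum is exactly 1.  This models
  the unassigned signal of real tissue spectra and serves two numerical
  purposes: (i) it gives mean normalization a fixed operating point, so
  planted levels live directly on the published normalized-area scale;
  (ii) being spread over ~2 ppm it has minimal leverage on Euclidean
  distances and contributes exactly zero to every window integral.  In the
  rare sample whose metabolite load alone exceeds the area budget the
  background is clipped at zero and that sample's recovered levels shrink
  under normalization, as they would in reality.
* **Lipids**: Gaussian peaks (FWHM 0.01 ppm) at 1.58, 2.02, 2.25, 2.80 and
  4.31 ppm — inside the five excluded windows — with amplitudes uniform up
  to 20× the tallest metabolite peak.  They are removed completely by
  preprocessing; a dedicated test asserts bit-level equality of the
  preprocessed matrix with and without them.
* **Noise and gain**: additive Gaussian noise per point (SD = 0.1 % of the
  cohort-mean spectrum's maximum), then a per-sample multiplicative gain
  ~ LogNormal(0, 0.3²) emulating sample weight / tumor-cell fraction.
  Mean normalization cancels the gain exactly.

### Calibration

Planted levels are in the arbitrary units of the published table
(integrated peak areas of mean-normalized spectra; quantified areas are
expressed per 0.0005 ppm of integrated area, decoupled from the grid
step).  A scalar per-metabolite scale `s_m` maps level units to intensity:
the calibration composes the noiseless cohort-mean spectrum, runs the
*actual* preprocessing + window integration, updates
`s_m ← s_m · target_m / recovered_m`, and repeats until the maximum
relative error is below 0.1 % (error after 10 iterations).  Because
recovery is linear in the scaled levels and the window-leak matrix is
strongly diagonally dominant, this fixed point is the exact leak-corrected
solution; with the default Gaussian lineshape it converges in 2–3
iterations.  Zero targets receive scale 0.

### What the generator does and does not emulate

It reproduces: the three-cluster mean/dispersion structure of the 18
quantified metabolites on the normalized scale; lipid contamination
confined to the excluded windows; per-sample gain; expression data in which
only Mc1 differs (planted shifts of 0.8–1.6 log2 units in ~7.5 % of genes,
majority down in Mc1, and exactly zero Mc2-vs-Mc3 effects); an ECM-like
gene set carrying signal among null sets; per-cluster PAM50/RPPA/clinical
multinomials matching the published proportions with NA included (samples
never profiled on a platform are folded into NA, so conditional-on-typed
fractions match the printed tables).

It does not emulate: free-induction decays, phasing, baseline roll or
chemical-shift misalignment; sample exclusion for high lipid content;
within-cluster metabolite-metabolite correlation (off by default); any
real gene-gene covariance, batch ("hospital") structure, or survival
fields.  Passing tests therefore demonstrate the statistical machinery on
data with the published *marginal* structure, not performance on real
spectra.

## Statistical components and numerical choices

* **Preprocessing**: region bounds inclusive, exclusion windows closed
  (boundary points removed); normalization strictly after exclusion.  No
  alignment or baseline correction is modeled (none is described for the
  original workup beyond these steps); the stages are composable functions
  so such hooks can be added upstream.
* **Ward clustering**: scipy's Ward linkage; merge cost reported as
  ΔESS = height²/2 (for two singletons a, b: ‖a−b‖²/2).  An exhaustive
  greedy-ΔESS oracle (O(n³)) verifies tree identity at n = 8.  Cut labels
  are renamed deterministically by decreasing cluster size, then
  first-sample order.  In the end-to-end driver the labels are subsequently
  renamed by maximum-overlap assignment against the planted clusters,
  because the size-based rule would systematically call the largest cluster
  "Mc1" while the published Mc1 is one of the small clusters; the mapping
  is written to the run log.
* **PLS-DA**: NIPALS PLS2 on column-centered X and one-hot Y; sign
  convention: each weight vector's largest-magnitude element positive;
  prediction by argmax of predicted class scores; LV count = smallest
  within 1 binomial SE of the best mean 10-fold stratified CV accuracy;
  permutation p = (#{perm ≥ obs} + 1)/(B + 1) on the mean CV accuracy, with
  per-class p-values reported alongside (for the largest class the
  per-class permutation p is conservative by construction, since shuffled
  models drift toward majority prediction).  Wide matrices are projected
  onto the row space of the centered data (one SVD) before CV/permutation
  work — exact, since all quantities involved are inner products in that
  space.
* **Kruskal-Wallis**: tie-corrected H with chi-square reference
  (df = groups − 1); all-tied input returns H = 0, p = 1 by convention.
  At n = 9 the chi-square tail deviates from the exact permutation tail by
  several hundredths (tests assert agreement to 0.07 on a moderate toy, and
  exact H equality always); at the cohort sizes in scope the approximation
  is accurate.
* **"Significant between" patterns**: the mechanism behind the published
  pattern column is not stated; implemented as the three pairwise two-group
  rank tests, BH within each metabolite, gated by the omnibus BH-adjusted
  p ≤ 0.05, mapping {3 pairs → all; 2 pairs sharing X → "X vs rest";
  1 pair → that pair; 0 → NS}.
* **Fold change**: log2(cluster mean / cohort mean); the reference
  (unstated in the original figure) is the overall cohort mean, which makes
  the size-weighted mean of 2^FC exactly 1 per metabolite.
* **Fisher exact (r×c)**: two-sided rule = total null probability of tables
  with point probability ≤ the observed (standard r×c convention);
  exhaustive vectorized enumeration when the composition bound on the
  number of margin-compatible tables is ≤ 5×10⁶, otherwise Patefield
  margin-preserving Monte-Carlo with p̂ = (hits + 1)/(draws + 1).
  The default family replicates the published analysis: histology, tumor
  size, grade, node status, HER2, ER, PR, PAM50, RPPA (NA rows and all-zero
  rows dropped), one BH family of nine.  The published adjusted values are
  reproduced only up to a constant factor of ~14/9 on the subtype tests —
  the raw p-values agree, indicating the original family comprised about
  14 tests whose full composition is not recoverable from the published
  description.  The nine-test family is retained as documented.
* **SAM**: two-class d = (x̄₂ − x̄₁)/(s + s₀) with pooled s; multiclass
  numerator √(Σ n_k (x̄_k − x̄)²) with pooled within-class s; s₀ chosen from
  the 0,5,…,100 percentiles of s by minimizing the coefficient of variation
  of the MAD of d across 100 s-quantile windows; q-values = median
  permutation exceedance count / observed exceedance count at each gene's
  |d| (π₀ = 1, conservative), monotonized and clipped to [0,1]; the t-style
  statistic is implemented (a rank-based variant is a possible extension).
* **Signal-to-noise ranking**: |μ_A − μ_B|/(σ_A + σ_B) with each class SD
  floored at max(σ, 0.2·|μ|) (and 10⁻⁸ absolute) — the raw formula has no
  guard against near-zero variances.
* **GSEA**: weighted KS running sum with weight exponent 1 on the absolute
  ranking score, ties in the ranking broken by gene id; sets restricted to
  measured genes, sizes outside [15, 500] dropped (and reported); NES = ES
  divided by the mean |permutation ES| of the same sign; FDR q = ratio of
  sign-stratified permutation and observed tail fractions, clipped to 1;
  phenotype permutation only.  Note that with ~7.5 % of genes strongly
  differential, *random* sets legitimately attain low q — they inherit
  signal carriers — which mirrors the behavior of enrichment analysis on
  strongly structured cohorts; null calibration is asserted under label
  permutation, where the median number of q < 0.25 sets is 0.
* **Joint pathway test**: genes and metabolites pooled over a combined
  universe (disjoint namespaces); hypergeometric upper tail
  P(X ≥ hits); no topology weighting (the upstream tool's exact
  combination algorithm is not published); metabolite matching is exact on
  canonical names.

## Determinism

Every stochastic component takes a seed; the pipeline derives per-stage
child seeds from one root seed via `SeedSequence.spawn` in a fixed order.
Re-running with the same configuration produces byte-identical numeric
outputs (asserted in the test suite).

## Known limitations

* **Cluster recoverability ceiling.**  With independent zero-truncated
  normal levels at the published per-cluster means/SDs, the three clusters
  overlap substantially in spectral space: the Bayes-optimal classifier
  (true generative model, known parameters) reaches only ≈ 94 % accuracy
  and ARI 0.75–0.86 over repeated cohorts, and unsupervised Ward/Euclidean
  reaches ARI ≈ 0.3–0.6.  This is a property of summarizing clusters by
  marginal means/SDs: in the original cohort the cluster labels were
  *defined* by cutting the dendrogram, so they are self-consistent with
  the spectral geometry in a way independent marginals cannot encode.  A
  within-cluster common-factor correlation was evaluated and makes Ward
  recovery worse (elongated clusters are split across their long axis), so
  it is off by default.  The recovery test asserting ARI ≥ 0.9 on ≥ 9/10
  seeds documents this gap and is expected to fail.
* Realized SDs of high-dispersion metabolites sit below the configured
  values (truncation constraint, above), so rank-test power for
  scyllo-inositol-like metabolites is somewhat higher than the printed
  dispersions would suggest; the published non-significant metabolites
  remain non-significant in the default cohort.
* Cohort-level gene counts, PLS-DA accuracies and explained variances of
  the original study depend on the unpublished cohort and are treated as
  output-shape references, not reproduction targets.

## Problem sizes used by the tests and the acceptance script

The default cohort (228 samples, 7601 grid points, 2000 genes, 150
differential, 31 gene sets, 11 pathways) is used throughout; permutation
counts in tests are 100 (SAM), 200–500 (GSEA) and 39–999 (PLS-DA), and the
pipeline smoke tests use a coarser grid (step 0.001) and 300 genes.  The
acceptance script uses 10⁷ Monte-Carlo tables per non-enumerable Fisher
test and one default cohort; it completes in about a minute on one CPU.
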