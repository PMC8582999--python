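# Methods

## Model and procedure

`featde` tests two-group differential gene expression in two stages. First,
every feature (exon, transcript, or transcript equivalence class) is tested
on its own: counts `y_fj` are modelled as negative binomial with mean
`s_j · exp(b0_f + b1_f x_j)` — `s_j` the sample's RLE size factor used as an
offset, `x_j` the group indicator — and per-feature dispersion `α_f`. Second,
the K feature p-values of each gene are combined into one gene-level
p-value, Benjamini–Hochberg corrected across genes, and DEGs are called at
FDR < 0.05 (strict inequality; a gene at exactly 0.05 is not called).

The combination step is the methodological core. Fisher's statistic
`Σ −2 log p_i` is referred to `χ²(2K)` only when the p-values are
independent. Features of one gene are not independent: they share the
gene's expression level, so their counts — and under the null their
p-values — are positively correlated, which makes Fisher (and its weighted
Lancaster generalisation) anti-conservative exactly where the feature-level
approach is most attractive, at the exon level. Brown's correction keeps the
Fisher statistic but rescales the null to `c·χ²(f)` by matching its first
two moments: with `E = 2K` and `Var = 4K + 2Σ_{i<j} cov_ij`,

    f = 2E²/Var,    c = Var/(2E).

The marginal variance of each `−2 log p_i` is fixed at its theoretical value
4 (chi-square with 2 dof); only the off-diagonal covariance is estimated.
This keeps the independence limit exact: zero covariance gives `(c, f) =
(1, 2K)` and Brown collapses to Fisher. The empirical Brown method (ebm)
estimates the covariance nonparametrically: each feature's expression row is
transformed to `−2 log ECDF(x)` (right-continuous rank ECDF, `rank/S` with
'max' ranks, so values lie in (0, 1] and the transform cannot overflow) and
the sample covariance (S−1 denominator) of the transformed rows is used.

### Conventions and numerical choices

- **Lancaster quantile tail.** The per-feature chi-square quantile is the
  *upper-tail* quantile (inverse survival function). This is the only
  reading under which weight 2 maps `p` to `−2 log p` and Lancaster with all
  weights 2 reproduces Fisher, which is the identity the method is defined
  by. Weights are the raw mean normalized counts, not rescaled.
- **Clamping.** p-values below 1e-300 are clamped before logs/quantiles so
  statistics stay finite; p = 1 contributes 0.
- **K = 1.** Every combiner returns a single p-value unchanged, bypassing
  the chi-square round-trip; the identity is then exact rather than exact to
  one ulp.
- **Constant rows in ebm.** A constant expression row carries no dependence
  information; its covariance entries are set to 0 (feature treated as
  independent).
- **Degenerate empirical covariance.** If strongly negative empirical
  covariances drive the matched variance nonpositive, ebm falls back to the
  independence correction `(c = 1, f = 2K)` with a warning, degrading to
  Fisher rather than failing.
- **NB test.** Coefficients are fit by IRLS, vectorised across features;
  dispersion maximises the Cox–Reid-adjusted profile likelihood on a 41-point
  log grid over [1e-8, 100] with parabolic refinement, seeded by a
  method-of-moments estimate; two coefficient/dispersion alternations. The
  Wald statistic is referred to a t distribution with S − 2 degrees of
  freedom — a small-sample correction; against the normal reference the test
  is anti-conservative at typical group sizes. There is no shrinkage,
  independent filtering or outlier handling; any external per-feature table
  can be injected instead and flows through the identical aggregation path.
- **RLE size factors** are median-of-ratios with zero-containing features
  excluded from the reference, normalized to unit geometric mean. The
  normalization makes the factors' defining equivariance exact: scaling one
  sample's column by a factor moves that whole factor into its size factor
  relative to every other sample. (Without it the vector is identified only
  up to a common scale and no such statement holds.)
- **Filters.** "Low expression" means the feature's *mean* normalized count
  across all samples is below 1 (strict; min/max summaries are available).
  Genes with exactly one remaining exon after filtering are removed — their
  result cannot differ between feature levels — and when several feature
  levels are analysed jointly, the exon-level removal list is applied to all
  levels and a gene whose features all vanish at any level is removed from
  every level (set intersection of surviving gene sets).
- **ebm covariance source.** The gene's RLE-normalized feature counts (the
  matrix the rest of the pipeline uses); configurable by passing any other
  feature × sample matrix to `aggregate_to_genes`.
- **ROC/pAUC.** The ranking statistic is the gene-level p-value (the one
  score every scheme produces). Partial AUC integrates the ROC curve over
  specificity ∈ [0.8, 1] by trapezoid with tied scores forming a single
  step and linear interpolation at the boundary; it is reported
  unnormalized (maximum 0.2), with a normalized option off by default.
- **Mock FDR.** Each repeat draws `2·subset_size` samples without
  replacement from one group and halves them (for a 14-sample group and
  subsets of 7 the random split is what varies); the estimate is the median
  mock DEG count divided by the DEG count of the full between-group
  comparison on the same scheme. Zero between-group DEGs yield NaN.
- **Flattening** is exon-union: overlapping or bookended intervals are
  merged into maximal disjoint units (1-based inclusive coordinates),
  numbered 5'→3' on the gene strand. Sub-bin boundary splitting is out of
  scope. Cross-gene overlaps are reported and retained by default;
  exclusion is opt-in.

## Synthetic data

The generator emulates the data situation the method targets, not any
particular experiment. Counts for exon k of gene g in sample j are NB with
mean `depth_j · base_gk · L_gj · 2^{lfc_k·x_j}`:

- `depth_j` log-uniform on [0.5, 2], so RLE normalization is exercised;
- `base_gk` a lognormal gene baseline (median 50) times a lognormal exon
  profile (sdlog 0.5);
- `L_gj` a shared lognormal (gene, sample) random effect. The configured
  dispersion (default 0.1) is *split*: the shared effect carries variance
  `v = ρ·α` and the conditional NB dispersion is `(α − v)/(1 + v)`, so every
  exon's marginal excess dispersion equals α exactly while the expected
  count correlation between two well-expressed exons of one gene approaches
  ρ. Default ρ = 0.7: exons of one gene are strongly correlated in real
  data, and this dependence is precisely what distinguishes ebm from
  Lancaster. Measured correlations sit below ρ for weakly expressed exons
  (Poisson noise dilutes the shared signal).

Defaults: 14 samples per group (so the 7-vs-7 mock design uses a group
exactly), 10% DE genes, log2 effect 1. Patterns: `uniform` (all exons
shifted), `partial` (k = 2 of K exons shifted), `discordant` (~60% of exons
up, ~40% down at ±effect). For discordant genes the baselines of the
down-regulated exons are rescaled so the expected gene total is unchanged —
a fold f up adds more counts than a fold 1/f down removes, so equal
baselines cannot cancel; after rescaling, gene-level testing sees nothing
while more than half the exons move.

What the generator does not emulate: read-level effects (mappability,
positional bias), isoform-deconvolution uncertainty, batch effects, outlier
samples, and genes sharing features. Passing tests therefore show that the
statistical machinery behaves as designed under its stated model, not that
any particular real dataset will reproduce a given ordering.

## Problem sizes

The test and acceptance runs use deliberately moderate sizes chosen as the
package's own benchmark conditions: calibration of the combiners on 10,000
simulated genes (S = 500 data columns for the ebm covariance, where the
rank-ECDF bias is negligible); dependence checks on K = 8 duplicated
features; NB test calibration on 5,000 null features at n = 10 vs 10,
dispersion 0.1; power comparisons on 400 genes × 7 exons at 14 vs 14 over
five generator seeds with 10 mock splits each. All simulations are seeded
and bit-reproducible.

## Known limitations

- The NB Wald test is intentionally minimal: no dispersion shrinkage across
  features, so very short matrices (2–3 samples per group) are noisy; use
  the injection path with a shrinkage-based tool if that matters.
- ebm needs enough samples to estimate a covariance; with fewer than ~8
  samples total the estimated (c, f) are noisy and ebm drifts toward
  Fisher on average.
- Brown-type corrections address *positive* dependence well; strong negative
  dependence triggers the independence fallback.
- Multi-factor designs, continuous covariates and differential exon *usage*
  (relative, DEXSeq-style) are out of scope.
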