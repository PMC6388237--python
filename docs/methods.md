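# Methods

## Index model

Each monitoring record is condensed to `I = Σᵢ Iᵢ`, an unweighted sum of
dimensionless sub-indices. The three rules and their rationale:

* **General constituents** `Iᵢ = Cᵢ/Sᵢ`. Linear in the concentration and
  exactly 1 at the regulatory limit, so the sub-index reads directly as
  "fraction of the standard consumed". Limits are configuration (JSON or
  CSV), never constants in code; the bundled table carries the national
  drinking-water limits for the 16 routine indicators in their native
  units (e.g. arsenic 0.01 mg/L, fluoride 1.0 mg/L, turbidity 1 NTU).
* **pH** `I_pH = (C_pH − 7)/1.5`. The default keeps the printed sign
  convention, under which acidic water scores negative and the sub-index
  *reduces* the total; an `absolute` option (`|C_pH − 7|/1.5`) penalizes
  acid and alkaline deviations symmetrically. Both are exposed because
  the signed form, while the documented default, arguably understates
  acidity problems; swapping modes is a one-flag change.
* **Coliforms (TC, TCB)** `0` for a non-detect, else `ln(Cᵢ+1) + 1`.
  The rule is deliberately discontinuous at zero: the microbial standard
  is zero-tolerance, so the first detected organism jumps the score to
  ≈ 1 (one full standard-unit), with logarithmic growth thereafter. The
  logarithm base is pluggable (`ln` default, `log10` option); `ln` keeps
  the jump height at exactly 1 and the score strictly increasing.

Missing indicators are skipped by default (the sum runs over the
indicators present and `n_indicators_used` records how many), because
monitoring archives routinely have gaps; a `strict` policy turns any gap
into an error. Below-detection-limit tokens (`<0.01`) are parsed as
LOD/2 by default (options: zero, LOD) — the conventional substitution
when no distributional assumption is wanted. Note the skip policy means
totals from records with different indicator coverage are not strictly
comparable; `n_indicators_used` is carried in every result so users can
filter.

## Geostatistics

Ordinary kriging is implemented from scratch in the semivariance
formulation.

* **Empirical variogram**: Matheron's method-of-moments estimator on
  equal-width distance bins; default 15 bins to half the maximum
  pairwise distance. Bins with no pairs are dropped.
* **Model fit**: spherical (default), exponential, or Gaussian family,
  fitted by weighted least squares with weights N(h)/h² (uniform
  available). The exponential and Gaussian families use the effective-
  range convention (γ reaches 95% of the sill at the stated range, via
  the factor 3 in the exponent). Optimization is a bounded
  trust-region solve from a fixed 12-point start grid (nugget fractions
  × range fractions), so fits are deterministic with no seed. If the
  fitted range collapses to or below the shortest observed lag the model
  is observationally equivalent to pure nugget on those data, and is
  canonicalized to (nugget = fitted semivariance at the first lag,
  partial sill = 0). An all-zero empirical variogram returns a
  degenerate zero model with a warning.
* **Kriging**: the (n+1)×(n+1) system — pairwise semivariances bordered
  by the unbiasedness row — is LU-factorized once and reused for all
  targets; weights therefore sum to 1 to machine precision and
  zero-nugget prediction at a sample location is exact. γ(0) = 0 by
  convention, so the predictor with a nugget is still exact *at* data
  points but discontinuous around them (the textbook behavior).
  Kriging variances in [−1e−8, 0) are round-off and clamped to zero;
  anything more negative raises. Duplicate sample locations are named
  in the singularity error. The neighborhood is global: at the ~10²
  sample sizes this package targets, locality buys nothing.
* **Coordinates**: inputs are longitude/latitude; the default maps them
  to planar kilometres by an equirectangular projection about the data
  centroid, adequate at provincial scale (distance distortion well under
  1% over a few hundred km). A raw-degrees flag performs Euclidean
  distance on degrees directly for compatibility with naive GIS
  workflows. Anisotropy is not modeled.

## Cross-validation and metrics

Leave-one-out CV is the default flavor: each site is predicted by
kriging from all the others. The variogram is fitted once on the full
data (`fit_once`) — refitting per fold with n−1 ≈ n points changes
estimates negligibly while multiplying cost — with `refit_per_fold`
available. MAE, MRE and RMSE follow their standard definitions; MRE is
undefined at observed zeros, a hard error by default with an explicit
skip-with-warning policy. The agreement statistic

AC = 1 − n·RMSE² / Σ (|oᵢ − ō| + |eᵢ − ō|)², ō = mean of observed,

is algebraically Willmott's index of agreement d (since n·RMSE² =
Σ(oᵢ−eᵢ)²); the test suite asserts the identity on random vectors to
1e−12 rather than re-deriving d's properties. Both vectors are centered
on the *observed* mean, which is what makes the statistic ≤ 1 with
equality exactly at perfection.

## Group comparisons

Two-level factors (source, supply, season) use Welch's unequal-variance
t-test — chosen over the pooled test because monitoring strata are
unbalanced (surface-water groups can be a quarter the size of
groundwater groups) — with a pooled option; multi-level factors (year)
use classical one-way ANOVA. Statistics are computed from their explicit
formulas and p-values from the scipy t/F distributions; scipy's own
test functions serve as independent cross-checks in the suite. Raw
p-values are reported; a Bonferroni helper exists but is off by default.

## Synthetic data

The generator replaces an unpublished monitoring archive and defines the
conditions everything is tested under:

* **Design**: 128 sites × 2 seasons × 5 years (2007–2011) = 1280
  records; source and supply strata assigned per site-year with
  year-specific proportions (defaults ≈ 71–81% groundwater, ≈ 71–81%
  centralized, drifting across years as real networks do).
* **Spatial structure**: a site-level latent quality factor drawn from a
  Gaussian random field (covariance C(h) = sill − γ(h), Cholesky
  factorization with escalating jitter). Default spherical model,
  nugget 0.02, partial sill 0.25, range 2° on a ~7.5° × 4° bounding box.
* **Marginals**: general concentrations are lognormal around 0.4·Sᵢ with
  log-scale σ = 0.6 — right-skewed, mostly compliant, with occasional
  exceedances, which is what routine drinking-water archives look like.
  Group effects (surface +0.5, decentralized +0.5, year 2008 +0.5 on the
  log scale) shift the latent factor; the 2008 default follows the
  convention that the flagged year has a *higher* (worse) mean index.
  Coliforms are zero-inflated (80% non-detect, lognormal-ish integer
  counts otherwise); pH is normal(7.4, 0.3) truncated to (6, 9); each
  measurement is masked missing with probability 0.05.
* **Determinism**: every dataset is a pure function of (config, seed);
  fixtures regenerate byte-identically.

What the generator does *not* emulate: laboratory measurement error
distinct from natural variability, censoring correlated with
concentration, non-stationary trends, or clustered site placement
(available as an option but not default). Passing tests therefore
demonstrate the pipeline's internal correctness and its behavior under
idealized skewed/correlated/missing data — not performance on any real
archive.

## Test-condition choices

* **Variogram parameter recovery** uses a spherical model with a
  moderate nugget fraction (nugget 0.25, partial sill 0.75, range 0.3 in
  a unit square, n = 400). A near-zero nugget is weakly identified by a
  binned moment estimator at this n — the first bin center sits well
  above lag zero, so the nugget is an extrapolation — and recovery
  criteria on it would measure identifiability, not code correctness.
* **The high-agreement CV regime** uses a Gaussian-family field
  (nugget/sill = 1%, range 0.6, 128 points in the unit square): the
  canonical "smooth, densely sampled" configuration, where LOOCV AC
  lands around 0.97–0.99. The contrast field is pure nugget, where AC
  collapses toward 0.
* Group-test calibration runs 1000 null replicates and accepts rejection
  rates within 3.5 binomial standard errors of 5%.

## Numerical notes and limitations

* Gaussian-family covariance matrices are ill-conditioned at high
  sampling density; the simulation path retries Cholesky with jitter up
  to 1e−6 and the kriging path names the offending pair when a system is
  singular. A nonzero nugget regularizes both.
* The variogram fit is WLS on binned estimates, not REML; at small n the
  nugget/partial-sill split is noisy even when their sum is stable.
* MRE is scale-sensitive for observed values near zero; prefer MAE/RMSE
  when indices can vanish.
* ESRI ASCII export requires square cells (the format has one cellsize);
  rectangular grids must use CSV or GeoJSON.
* No health-risk banding of WQI values is provided, and no weighted or
  geometric-mean index variants — the aggregate is the plain unweighted
  sum by design.
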