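# Methods

## The subtraction model and its assumptions

The package estimates a two-latent-variable structural model over the
genetic covariance matrix of two case-control disorders, SZ-like and
BD-like. The shared factor (`PSY_shared`) loads on both traits and is
scaled to BD (loading fixed to 1); the specific factor (`SZ_specific`)
loads only on SZ and is scaled to SZ. Latent variances are fixed to 1,
factor covariance to 0, and residual variances of the observed traits to 0,
so all of each trait's genetic variance is carried by the factors and the
squared standardized loadings on SZ sum to 1. With these constraints the
model is just-identified: the closed forms in `subtraction.fit_loadings`
solve it exactly, and the iterative V-weighted discrepancy minimizer
`fit_loadings_wls` (Levenberg–Marquardt on Cholesky-whitened residuals) is
retained purely as an independent cross-check — its minimized discrepancy
is zero up to solver tolerance and its loadings agree with the closed form
to well below 1e-6.

Standard errors of the standardized loadings come from the delta method
applied to the jackknife sampling covariance `V` of `vech(S)`. Per-SNP
standard errors of the specific factor use the closed-form difference
variance with the cross-trait LDSC intercept supplying the per-SNP sampling
covariance, `cov_j = rho_cross · se_SZ,j · se_BD,j`. The uncertainty of the
stage-1 loading is not propagated into per-SNP SEs; with ~50k SNPs the
loading SE (~0.02) contributes negligibly to the per-SNP variance, and the
null-specific calibration test confirms the resulting p-values are
accurate to binomial error.

All per-SNP quantities live on the per-allele scale, recovered from
z-scores, reference allele frequencies, and effective sample sizes via
`beta = z/√(2pq·N)`, `se = 1/√(2pq·N)`. This makes the subtraction
identity `beta_SZ = lambda·beta_shared + beta_specific` exact row-wise and
makes the effective-sample-size inversion `N_j = (z_j/beta_j)²/(2 p_j q_j)`
an identity on constructed inputs. Under the scaling convention above the
shared factor is the BD genetic component, so its inferred effective N
equals BD's; the specific factor's effective N is
`1 / (1/N_SZ + lambda²/N_BD − 2·lambda·rho/√(N_SZ·N_BD))`, which with the
default study conditions (loadings 0.679/0.734, observed-scale SNP
heritabilities 0.24/0.16, effective N 117,498/101,962) evaluates to ≈65.7k.

## LD score regression

Heritabilities and genetic covariances come from weighted regressions of
`z_a·z_b` on `l_j·√(N_a N_b)/M` with a free intercept (diagonal cells are
the chi-square regression; intercepts absorb confounding and sample
overlap). Weights are the standard heteroskedasticity × overcounting form,
iterated twice from an initial `1/l` fit; SNPs with chi-square above
`max(80, 0.001·N)` are excluded from the regression only. The sampling
covariance of all cells is a joint delete-one-block jackknife over 200
contiguous blocks shared across every pair regression, so `V` is coherent;
it is projected to the PSD cone by eigenvalue clipping when numerical
asymmetry produces a tiny negative eigenvalue (the Frobenius distance of
the adjustment is logged). All quantities stay on the observed/effective-N
scale; genetic correlation is scale-invariant, so no liability conversion
is performed.

One practical consequence of the small synthetic genome: per-SNP
non-centrality scales as `N·h²·l/M`, so pairing a large effective N with a
small M produces unrealistically large chi-squares and lets the outlier cap
bite; small studies (e.g. the CLI example) should scale N down with M.

## The synthetic study

The generator is the package's definition of the study conditions. Per-SNP
latent scores (shared, specific, IQ, EA) are drawn from a 4×4 correlation
matrix whose defaults are the reported latent-level genetic correlations
(shared/specific vs IQ: −0.07/−0.24; vs EA: +0.11/−0.06; IQ–EA 0.70), then
scaled to trait effects through the loadings (0.679, 0.734) and SNP
heritabilities (SZ 0.24, BD 0.16, IQ 0.19, EA 0.12). These defaults are
internally consistent: the implied observed-trait correlations (SZ–IQ
−0.22, SZ–EA ≈ +0.03, BD–EA +0.11, SZ–BD 0.679) match the reported
observed-scale estimates without further tuning.

LD is block-diagonal AR(1) (signed correlation `ρ^|i−j|` with
`ρ = √decay`, default decay 0.8 in r², 50 SNPs per block) followed by a
stretch of LD-free singleton SNPs (default half of the genome). The
singletons emulate the genome's low-LD fraction; without them the LD-score
regressor has almost no spread near `l = 1` and the intercepts are weakly
identified, which in turn destabilizes the overlap correction and the
effective-N inversion. Within each block, z-scores are
`√N · R·beta_true + L·e` with `R = L·Lᵀ`, which reproduces the LDSC
expectations for the mean chi-square and the cross-trait intercept exactly;
noise is correlated across the two case-control traits by `overlap_rho`
(default 0). All draws flow from one seed through a documented
`SeedSequence` split (frequencies/alleles, effect sizes, noise, panel).

The genotype panel uses continuous imputed-style dosages from the block
model's Gaussian copula (`2p + √(2pq)·L·ξ`, clipped to [0, 2]) so that
clumped score weights keep their LD tagging. Clipping shrinks the dosage
mean slightly for allele frequencies near the boundary (≲0.05 absolute).
Panel phenotypes couple to the true factor genetic values with standardized
couplings whose defaults are the headline standardized score effects
(education years: −0.13 specific / +0.14 shared; fluid intelligence:
−0.09 / −0.08, signs from the truth correlation matrix), plus small sex,
year-of-birth and six PC-like covariate effects, plus noise; education
years are rescaled to mean 14, SD 5 and also emitted as qualification code
lists (a shipped default code→years mapping — the package's own default,
not any cohort's table) so the maximum-across-visits derivation step is
exercised end to end.

What the generator does *not* emulate: realistic human LD maps or the MHC,
allele-frequency–dependent architecture, imputation error, population
stratification, relatedness, or ascertainment. Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
model's own assumptions, not robustness to real-data pathologies.

## Downstream stages

Genetic correlations use `rg = S_ab/√(S_aa·S_bb)` with delta-method SEs
from `V` and two-sided normal p-values; the BH family is the set of
distinct unordered pairs of a single call (self-correlations reported but
never in the family). Polygenic weights are clumping + thresholding
(greedy smallest-p index SNPs, r² ≥ 0.1 within 500 kb removed; default
p-threshold 1 keeps all clumped SNPs), with the weights interface accepting
externally computed files so shrinkage-based weights can be dropped in.
Because p-values clamp at the smallest positive normal double for very
strong signals, clumping breaks p ties deterministically by genomic
coordinate. MR instruments are genome-wide-significant clumped exposure
SNPs (r² 0.001, 10 Mb) harmonized to the outcome with palindromic SNPs
dropped; the IVW primary is multiplicative random effects (SE inflated by
`max(1, √(Q/df))`), MR-Egger re-signs exposures positive and uses a t(n−2)
reference, the weighted median is the centered-CDF weight-0.5 quantile with
delta-method ratio weights and a seeded parametric bootstrap SE (1000
draws), and the penalised variant multiplies weights by
`min(1, 20·p_j)` with `p_j` the chi-square(1) tail of the instrument's Q
contribution at the unpenalised estimate. `I²_GX` is computed as
`max(0, (F̄−1)/F̄)` from the mean instrument F-statistic.

## Numerical and design choices

- Munging defaults: MAF ≥ 0.01, drop strand-ambiguous and non-ACGT
  alleles, first occurrence kept for duplicate ids; coordinates 1-based.
  Files are written with `%.17g` and read with round-trip float parsing so
  numeric round-trips are bit-exact.
- P-values below double underflow are clamped to the smallest positive
  normal; anything downstream that needs resolution works with z-scores.
- Negative implied variances (specific-factor variance from stage 1,
  per-SNP difference variances from an excessive cross intercept) raise
  errors rather than being clamped.
- The generator's latent correlation matrix is validated symmetric PSD with
  unit diagonal before any sampling; standardized loadings may sit at the
  degenerate corners 0/1 to express the null models used in calibration.
- Dosages are single precision (memory-bandwidth bound at panel scale);
  scores are standardized in double precision, so score mean/SD are exact
  even though individual dosage products round at ~1e-7.
- The fit-shaped stages are estimator classes (`LDScoreRegression`,
  `GwasBySubtraction`, `IVWEstimator`, `EggerRegression`,
  `WeightedMedianEstimator`) with scikit-learn parameter semantics and
  trailing-underscore fitted attributes; IO, generation and one-shot
  derivations remain functions.

## Test design

Statistical unit tests on a single seeded run use 3-SE bounds (a 2-SE bound
on a single draw fails by design ~5% of the time per quantity); the
multi-seed acceptance checks use the stated seed-count margins (≥18/20,
≥19/20). Calibration checks that quote binomial error bars are evaluated on
the LD-free singleton SNPs, where rejections are independent and the
binomial SE is the right yardstick; LD-block SNPs would inflate the
variance of the rejection fraction without biasing it. Problem sizes — a
50,000-SNP genome, four traits with effective N around 10⁵, a
10,000-individual panel over 5,000 panel SNPs, 20-seed recovery loops —
were chosen as the smallest study at which LD score regression is stable
and the headline effects are well-powered.

## Known limitations

- The LD model's score distribution is far narrower than a real genome's;
  intercept SEs are correspondingly optimistic relative to real data.
- Effective-N inference for the shared factor returns the BD effective N
  by construction; conventions that rescale latent GWAS by residual factor
  variance would give different values.
- The MR stage treats genetically correlated traits as exposure/outcome
  pairs; under the infinitesimal generator, nonzero "causal" estimates
  between correlated traits reflect correlated pleiotropy, which is exactly
  the heterogeneity signature (large Cochran's Q) the diagnostics flag.
- The contamination-mixture / constrained-ML MR estimator and multivariable
  MR are not implemented; shrinkage-prior (MegaPRS-style) polygenic weights
  are replaced by clumping + thresholding, which preserves the
  sign/direction conclusions the score stage is used for.
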