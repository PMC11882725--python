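# Methods

## The problem

A battery of cognitive-test GWAS summary statistics shows a genetic
*positive manifold*: every pair of tests is positively genetically
correlated, because a general genetic factor ("genomic g") runs through all
of them. `gsubtract` implements the machinery to (i) estimate that factor
from summary statistics alone, (ii) residualize each test's per-SNP
association statistics for it (GWAS-by-subtraction), and (iii) quantify how
the genetic correlation landscape changes once the shared factor is removed.

## Model and estimation chain

**LD score regression.** For traits a, b with association statistics
`z_a, z_b` over variants j with LD scores `l_j`,

    E[z_aj * z_bj] = intercept + (sqrt(n_a n_b) * cov_g / M) * l_j,

so the genetic covariance on the observed scale is `slope * M / sqrt(n_a
n_b)` (the univariate case is the chi-square regression and `h2 = slope * M
/ n`). Weights follow the canonical two-step scheme: an unweighted
first-pass slope supplies a provisional heritability (clipped to [0, 1]) for
the heteroskedasticity term `1/(l * (1 + n_a h2_a l / M)(1 + n_b h2_b l /
M))`; LD scores are floored at 1. The intercept is always free; it absorbs
confounding and sample overlap.

**Joint block jackknife.** All k(k+1)/2 regressions share one partition of
the variants into contiguous blocks (default 200, auto-reduced to
`floor(m/50)` on small panels). V is the jackknife covariance of the
leave-one-block-out estimates of *all* entries of vech(S) jointly, so
cross-entry sampling dependence is retained — this is what the structural
model's sandwich standard errors and fit statistics need. Deleted-block
fits reuse the full-sample weights (fixed-weight jackknife), which keeps the
per-block refits exactly linear and lets the engine compute them from block
sufficient statistics without re-scanning the data.

**Common-factor model.** `Sigma(theta) = lambda lambda' + diag(u)` with unit
latent variance, fitted by DWLS: minimize `(s - sigma)' diag(V)^-1 (s -
sigma)` over the k(k+1)/2 unique moments; the full V enters only the
sandwich covariance `(D'WD)^-1 D'W V W D (D'WD)^-1`. Maximum likelihood is
available as an alternative estimator. Optimization is L-BFGS-B with an
analytic Jacobian from a principal-axis start (leading eigenpair of the
standardized S) plus a flat start and jittered restarts; a flat start alone
can land in local optima when loadings are strongly heterogeneous. The
reported solution is standardized per trait by its model-implied total
variance, which enforces `loading^2 + residual = 1` exactly; the factor is
oriented so the mean loading is positive. Negative residual variances
(Heywood cases) are flagged, not constrained, unless `bound_residuals` is
set. Model chi-square is the V-weighted residual quadratic form (df =
k(k+1)/2 − 2k), with CFI against the diagonal independence model and SRMR on
the correlation metric; these are descriptive.

**Per-SNP residualization.** Each variant's standardized SNP–trait
covariances `c_t = z_t / sqrt(n_t)` are modelled with two paths, SNP→factor
(`b_g`) and SNP→residual of one target (`b_r`):

    c_t = lambda_t b_g + [t = target] b_r,

solved by weighted least squares with weights `n_t` (the inverse sampling
variances; cross-trait sampling covariance is zero for non-overlapping
GWAS). The measurement model is estimated once at the panel level;
uncertainty in the loadings is propagated into the per-SNP standard errors
by the delta method. `b_r` with its SE is the g-corrected statistic. The
factor GWAS uses the one-path model (SNP→g only). An exact per-SNP re-fit
of the full expanded model is provided as an audit mode; it is
box-constrained because the unconstrained expanded fit can escape to a
degenerate Heywood manifold (|lambda| huge, u deeply negative) that
reproduces S exactly with meaningless paths.

**Effective sample size.** Corrected effects are written on the per-allele
scale; `N_eff` is the mean of `1 / (SE^2 * 2p(1-p))` over variants with
minor-allele frequency in (0.1, 0.4) (configurable), the standard recipe for
summary statistics of model-derived traits. It is what downstream LDSC of
the corrected files uses as n.

## The synthetic test bed

The generator draws a one-factor architecture on the standardized-genotype
scale: factor effects `alpha_j ~ N(0, 1/m)`, residual effects `delta_tj ~
N(0, Psi/m)` with residual correlation matrix Psi (identity by default),
causal effects `beta_tj = sqrt(h2_t)(lambda_t alpha_j + sqrt(1-lambda_t^2)
delta_tj)`, so `sum_j E[beta^2] = h2_t` and the implied genetic correlation
is `lambda_a lambda_b + sqrt(u_a u_b) Psi_ab`. LD is block-exchangeable:
within a block of B variants every pair has correlation rho_b, giving the
exact LD score `l_j = 1 + (B-1) rho_b^2` and an exact O(m) convolution
`R beta = (1-rho) beta + rho * blocksum(beta)`. Observed statistics are
`z = sqrt(n) R beta + eps`, `eps ~ N(0, R)`, independent across traits.

One numerical point matters: with a single rho for all blocks every variant
has the same LD score and the LDSC slope is unidentifiable. The default
study condition therefore draws per-block rho ~ Uniform(0.2, 0.8) (mean
0.5); a scalar rho remains available for closed-form checks.

Default panel: 12 traits with standardized loadings 0.26–0.92 (mean 0.66,
mean squared loading 0.468), SNP heritabilities averaging 0.16, GWAS sample
sizes 15,000–35,000, m = 20,000 variants in blocks of 10 — the scale and
shape of a mixed verbal/nonverbal cognitive battery, shrunk to desk size.
External traits are generated against the same latent draws with stated
genetic correlations to the factor and to one trait's residual.

What the generator does **not** emulate: realistic LD maps, allele-frequency
-dependent architectures, liability-scale binary traits, sample overlap
(available only as an option), population stratification, and imperfect
imputation. Passing tests therefore demonstrate estimator correctness under
the stated model, not robustness to real-data pathologies.

## Known structural properties and limitations

**Residual leakage.** With k traits the per-SNP solve cannot isolate one
residual among k+1 latent quantities. The corrected target receives each
non-target trait's residual with coefficient ≈ −1/(k−1) (equal-loading
case). Consequences, all verified by simulation at n = 500,000 where
sampling noise is negligible:

* pairwise genetic correlations among corrected traits carry a negative
  bias ≈ −1/(k−1) ≈ −0.09 at k = 12 — part of why the post-correction mean
  correlation is slightly negative rather than zero even with independent
  residuals in truth;
* an injected residual correlation of +0.4 between two traits is recovered
  post-correction at ≈ +0.27 (attenuated by the same mechanism plus the
  factor absorbing part of the injected covariance), −0.4 at ≈ −0.48;
* the factor GWAS correlates with corrected traits through shared leakage;
  for the one-path factor model this stays within ±0.05 for low and
  moderate loadings but reaches ≈ −0.13 for a 0.92-loading target, whose
  own residual is tiny.

The exact per-SNP re-fit has the identical leakage; it is a property of the
estimand, not of the fast solve. The fast solve and the full re-fit agree to
≈ 2.6e-4 when the measurement model is at reference precision (SE(S) ≈
5e-3); the gap grows with per-SNP power relative to that precision, because
a strongly associated SNP can visibly pull the per-SNP re-fit's measurement
parameters — a regime real GWAS panels (millions of variants, mean
chi-square near 1) do not enter.

**The loading-difference correlation.** Every pair's change in genetic
correlation after correction contains the removed factor term
−lambda_a lambda_b, which is mechanically correlated with
|lambda_a − lambda_b| (≈ +0.5 for loadings spanning 0.26–0.92). A near-zero
loading-difference correlation is therefore only a clean "null" when
loadings are tightly clustered; with spread loadings the statistic is
informative about how much of the landscape change is *not* mechanical.

**Other numerical choices.** PSD smoothing of S floors eigenvalues at 0 and
is applied only when the minimum eigenvalue < −1e-8; genetic correlations
are formed from the raw (un-smoothed) entries so each equals its pairwise
LDSC ratio, with NaN (never imputation) where a heritability estimate is
non-positive. Sign flips are counted both raw and with a 1-jackknife-SE
noise rule. Means over correlation matrices are unweighted over defined
pairs. Variant matching is by ID only; positions are carried but unused.
QC defaults (MAF ≥ 0.01, INFO ≥ 0.9, chi-square ≤ 80, drop strand-ambiguous)
follow standard munging practice and are configurable.

## Problem sizes

Module tests run on 2,000–5,000-variant panels; the statistical validation
experiments use the default m = 20,000 / n = 20,000 condition with 8–100
replicates per experiment, and the whole suite completes in about a minute
on one CPU. The end-to-end pipeline at the default scale runs in a few
seconds.
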