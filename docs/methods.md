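# Methods

## Structural model and what the estimator assumes

The package treats one exposure and one outcome, measured by GWAS in
two non-overlapping cohorts, under an omnigenic architecture: every SNP
j carries a standardized effect β_j ~ N(0, σ²_β/p) on the exposure and
a direct (horizontally pleiotropic) effect γ_j ~ N(0, σ²_γ/p) on the
outcome, with β ⟂ γ, and the exposure causes the outcome with scalar
effect α. Phenotypes have unit variance, so σ²_β is the exposure
heritability and α²σ²_β + σ²_γ the genetic share of outcome variance;
residual variances are 1 − σ²_β and 1 − α²σ²_β − σ²_γ, which must be
positive. Intercepts are handled by centering phenotypes before the
per-SNP marginal regressions and therefore never appear in summary
statistics.

Key assumptions, all inherited by anything fit with `fit_omr`:

* the two cohorts share one effect vector β (no gene–environment
  heterogeneity between them) and do not overlap, so the z-score noise
  terms e_x, e_y are independent;
* pleiotropy is *uncorrelated* with instrument strength (the
  InSIDE-type condition is strengthened to full independence of β and
  γ); directional pleiotropy with E[γ] ≠ 0 is not modeled;
* LD does not cross block boundaries. Within blocks it is arbitrary
  (taken from the panel); across blocks the composite likelihood treats
  z-scores as independent. Mild cross-block leakage biases the
  curvature, which is why standard errors never come from the Hessian
  (see below);
* causality is unidirectional (exposure → outcome); no reverse or
  bidirectional estimation is attempted.

## Composite likelihood and its factorization

For a block with m SNPs and shrunk panel correlation R, the stacked
(z_x, z_y) vector is zero-mean Gaussian with

    Σ_xx = a R² + R,  Σ_yy = b R² + R,  Σ_xy = c R²,
    a = n_x σ²_β/p,  b = n_y(α²σ²_β + σ²_γ)/p,  c = √(n_x n_y) α σ²_β/p.

All three pieces are polynomials in R, so with R = U Λ Uᵀ the rotation
(w_x, w_y) = (Uᵀz_x, Uᵀz_y) decouples the density into m independent
bivariate normals with covariances
[[aλ²+λ, cλ²], [cλ², bλ²+λ]] per eigenvalue λ. These 2×2 matrices are
positive definite whenever λ > 0, because c² ≤ ab by
Cauchy–Schwarz on the variance components. The implementation computes
one eigendecomposition per block and caches the rotated scores; a full
likelihood evaluation is then O(p) vector arithmetic and never forms a
matrix inverse. With a single all-SNP block this is *exactly* the
dense joint multivariate-normal log-density (tested to 1e-8), so the
factorization is a speedup, not an approximation.

Block weights default to w_b = 1, which preserves that dense-oracle
equivalence on independent blocks; w_b = 1/m_b is available for
architectures with very uneven block sizes.

## Optimization and inference

Parameters are optimized as (α, log σ²_β, log σ²_γ) — the log scale
enforces positivity without clipping — by Nelder–Mead from
method-of-moments starting values (the R ≈ I moment identities; a weak
default with a warning if mean z_x² < 1.05). Convergence uses
parameter and likelihood tolerances of 1e-6 and 1e-8. A fit whose
variance component lands at the 1e-8 floor is flagged `boundary`
rather than silently truncated; non-convergence returns
`converged=False` with a warning rather than raising.

Standard errors come from the delete-one-block jackknife,
se² = ((B−1)/B) Σ_b (α̂₍₋b₎ − ᾱ)², with each leave-one-out fit warm-
started at the full-data optimum. Composite likelihoods are known to
misstate curvature-based variances when their independence working
assumption is imperfect; the jackknife is assumption-light and is
itself validated by the type-I calibration test (200 null replicates,
rejection rate 0.045 against a nominal 0.05, inside the exact binomial
95% band [0.024, 0.088]). Wald p-values are computed with log-space
normal tails (`log_ndtr`/`ndtri_exp`), so magnitudes like 1e-32 — and
far smaller — are exact; every p ↔ z conversion in the package goes
through the same functions.

## LD blocks and shrinkage

Blocks are contiguous windows of 50 SNPs by default (remainder merged
into the last window, never crossing chromosomes), or the generator's
sidecar boundaries when present. Each R is the empirical panel
correlation shrunk as (1−λ)R + λI with λ = max(0.05, m/n_ref): the
empirical correlation is PSD, so every eigenvalue of the shrunk matrix
is at least λ, guaranteeing a usable factorization even when the block
size approaches the panel size. Disabling shrinkage with m > n_ref is
refused loudly.

## Harmonization rules

Alignment to the panel is by SNP id; effect signs flip when the
effect/other alleles are swapped, strand flips resolve through base
complements, and anything else is dropped as a mismatch. Palindromic
SNPs (A/T, C/G) are oriented by allele-frequency agreement and dropped
outright when the panel frequency lies in [0.4, 0.6] (frequencies too
close to 0.5 cannot resolve strand). The QC order is palindrome →
MAF < 0.01 → optional |z| cap; the filters are non-interacting set
predicates, so their order does not change the retained set, and every
removal is counted in a per-filter log. Per-SNP sample sizes collapse
to the median scalar because the covariance algebra uses scalar n_x,
n_y. Fewer than 100 retained SNPs (configurable) is an error, not a
silent small-sample fit.

## Mixture-grid replication estimator

A deliberately simple profile method used as a cross-check on the
composite-likelihood estimate. Instruments are genome-wide-significant
exposure SNPs (p < 5e-8), greedily clumped at panel r² < 0.1 within
blocks. At each grid point θ the residuals t_j = β_y,j − θ β_x,j with
known variances s_j² = se_y,j² + θ² se_x,j² are fit by EM to
π₀ N(0, s_j²) + (1−π₀) N(0, s_j² + τ²); the causal estimate is the θ
maximizing π₀ (ties toward the smallest |θ|). This is a two-component
simplification of the four-component bivariate mixture family it
imitates: it reproduces the θ-vs-null-mass profile but not that
method's asymptotic standard errors, and it is reported without a
p-value. Residuals are noise-normalized inside the EM so the profile
is exactly equivariant under common rescaling of all (beta, se); the
τ² floor of 1e-6 lives on that normalized scale. The default grid
[−1, 1] in steps of 0.005 comfortably brackets effect sizes up to
|α| ≈ 0.5.

The profile can only localize θ to roughly s/sd(β_x) — the residual
noise scale over the instrument-effect scale. Grid-step localization
therefore presumes strong instruments; the instrument generator's
defaults (per-instrument |z| ≈ 100, as for top cis-acting variants of
molecular traits) put it in that regime, and weak-instrument panels
will produce a correspondingly flat, less informative profile.

## Synthetic data: what it does and does not emulate

The generator produces reference panels (latent AR(1) Gaussians
thresholded to diploid haplotypes at uniform-MAF frequencies,
independent across blocks) and paired summary statistics, either by
simulating individual-level cohorts and running the marginal
regressions (the slow oracle path) or by drawing block z-scores
directly from the implied Gaussian law. The two samplers share one law
and are tested against each other. The summary sampler deliberately
uses the same shrunk panel LD matrices the estimator rebuilds, so
simulation and inference agree on what "the LD" is; this makes
recovery and calibration tests exact model checks rather than mixed
model-plus-LD-estimation checks.

Not emulated: realistic human LD maps and MAF spectra, case/control
liability-scale traits, sample overlap, population stratification, and
directional pleiotropy. Passing tests therefore demonstrate internal
correctness of the estimator under its own assumptions — not
robustness to the many ways real GWAS data violate them.

Default study conditions (and the sizes the test suite runs): 20 000
SNPs in 400 blocks of 50, AR(1) ρ = 0.5, panel of 500, n_x = 50 000,
n_y = 30 000, α = 0.2, σ²_β = 0.3, σ²_γ = 0.05. The type-I suite uses
5 000 SNPs in 100 blocks over 200 replicates. Exposure heritability
0.3 is a generator choice in the plausible range for heritable complex
traits, surfaced in `SimulationConfig`, not a claim about any
particular dataset.

## Cascade design

Round 1 screens the exposure against K mediators at α/K; survivors
become round-2 exposures against M outcomes at α/(M·k), with k the
realized survivor count — the denominator adapts so the familywise
level covers exactly the tests performed. Nominal findings (p < α but
above the Bonferroni layer) are flagged separately rather than mixed
with survivors. Failures of individual targets become error rows in
the report, never silent drops; a round where every target fails
raises. 95% intervals use the exact 0.975 normal quantile
(1.959964...), with rounding applied only at serialization.

## Known limitations

* Cross-block LD leakage is ignored; very long-range LD (e.g. MHC)
  should be handled by supplying explicit block boundaries or excluding
  the region upstream.
* The pleiotropy statistic reported is the outcome-variance fraction
  σ̂²_γ, not a count of pleiotropic SNPs; under this model every SNP is
  infinitesimally pleiotropic, so a SNP-fraction is not identified.
* The jackknife SE is mildly conservative at small block counts (it
  over-covered slightly in calibration runs); with fewer than ~20
  blocks, p-values should be read cautiously.
* Sample overlap between cohorts induces correlated noise (a non-zero
  term in Σ_xy) that the model omits by design.
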