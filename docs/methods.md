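# Methods

## Thermal performance curves

The package quantifies a unimodal growth-rate response to temperature
with the four-parameter Sharpe–Schoolfield model in its explicit-peak
form:

    B(T) = b0 · exp(−E/k · (1/T − 1/Tref))
           / (1 + E/(ED−E) · exp(ED/k · (1/Tpk − 1/T)))

with the Boltzmann constant k = 8.617×10⁻⁵ eV/K.  Temperatures are
kelvin internally (CSV input in °C is shifted by +273.15); rates are
s⁻¹ (per-day input divided by 86 400).  Parameters and defaults:

- `b0` (s⁻¹): rate at the reference temperature before deactivation;
  sets the curve's vertical offset.  Must be positive.
- `e_act` = E (eV): steepness of the rising branch — the organism's
  thermal sensitivity over its operational range.
- `t_pk` = Tpk (K): the exact argmax of the curve under this
  parameterization.
- `e_d` = ED (eV): steepness of the fall above the peak.  The factor
  E/(ED−E) requires ED > E; parameter sets with ED − E < 10⁻⁶ eV are
  rejected as numerically singular.
- `t_ref` = Tref (K): normalization temperature, 0 °C or 10 °C in
  practice.  Because the fitted `b0` only approximates the curve value
  at Tref, the trait used downstream under the name "B0" is B(Tref)
  evaluated from the fitted curve.

Derived shape quantities: Bpk = B(Tpk) (closed form, no search) and
the operational niche width Wop = Tpk − T_half, where T_half is the
rising-branch temperature at half the peak rate, found by bracketed
root finding (Brent, tolerance 10⁻⁶ K) on [Tpk − 150 K, Tpk].  If the
curve has not dropped to half height 150 K below the peak the value is
recorded missing rather than extrapolated into an unphysical range.

## Fitting and quality control

Nonpositive rates are removed before fitting (the model is strictly
positive); series with fewer than four positive points are skipped.
Fitting is bounded nonlinear least squares (trust-region reflective,
`x_scale='jac'`, tolerances 10⁻¹⁵ — parameter magnitudes span nine
orders, and looser settings demonstrably stall short of the optimum).
Bounds: b0 ∈ (10⁻¹⁰, 10³), E ∈ (0.01, 10) eV, ED ∈ (E+10⁻³, 50) eV,
Tpk within the observed temperature range ±10 K.  Multi-start
schedule: E ∈ {0.3, 0.65, 1.2} eV; Tpk at the temperature of the
observed maximum and ±3 K; ED = 3E; b0 from the rate nearest Tref
scaled by the Arrhenius factor.  Lowest SSR wins, ties to lower E.
The parameter covariance is the Gauss–Newton estimate
SSR/(n−4)·(JᵀJ)⁻¹.

Filters: fits with R² < 0.5 are dropped; at Tref = 10 °C fits with
Tpk < 10 °C are also dropped (their B(Tref) would sit on the falling
branch).  Data-coverage flags mark parameters unidentifiable from the
sampled temperature range: E missing with < 3 points below the fitted
peak; Tpk and ED missing with < 2 points above it; B0 inherits from E,
Bpk from Tpk, Wop from either.  These flags feed the mixed model's
missing-at-random machinery, so partially sampled curves still
contribute.

## Trait transforms and uncertainty

The six traits enter the comparative analysis as B0^¼, ln E, Tpk²,
ln Bpk, ln ED, ln Wop (transforms toward normality).  Variances are
first-order delta method; for B0 = B(Tref) and Bpk the inner variance
is propagated through a central-difference gradient of the curve with
respect to the four fitted parameters (at the peak the moving-argmax
contribution vanishes because dB/dT = 0 there).  Wop has no analytic
form, so its ln-scale variance comes from a nonparametric bootstrap:
(T, rate) pairs resampled with replacement and refit from the original
optimum (default 100 replicates).  Case resampling was chosen over
residual resampling because heteroscedasticity across a TPC is the
rule, not the exception; the variance is taken directly from the
ln Wop replicates with no additional delta step.  Rates are positive,
so the quartic root needs no sign handling.

## Phylogenetic relatedness

Trees are read as Newick (dendropy), pruned to the analysis taxa, and
converted to a relatedness matrix A with A[i,j] = MRCA depth / tree
height, computed as (depth_i + depth_j − d_ij)/2 from patristic
distances.  Trees are scaled to unit height — the time calibration is
relative, and unit height makes heritable and residual variance
components directly comparable (diag(A) = 1).  Tip-depth spread beyond
1% of height triggers a non-ultrametric warning but not an error.  The
inverse is dense with a 10⁻¹⁰ jitter fallback; at the package's
problem sizes (tens to a few hundred taxa) sparse ancestral-node
formulations buy nothing.

## The multi-response phylogenetic mixed model

For observation i (one TPC) of species s(i) with trait vector y_i:

    y_i = Bᵀx_i + u_{s(i)} + e_i,   e_i ~ N(0, R)
    vec(U) ~ N(0, G ⊗ A)
    w_ij = y_ij + m_ij,  m_ij ~ N(0, v_ij)   (v_ij known)

Fixed-effect structures: per-response intercepts, plus optionally
|latitude|, a quadratic in standardized latitude, a marine/freshwater
indicator, both, or arbitrary named covariates (the marine
thermal-regime variants).  Continuous covariates are centered and
scaled, with the scaling recorded for coefficient back-transformation.
Each covariate gets a distinct coefficient per response.

All full conditionals are conjugate, giving a blocked Gibbs sampler:
latent true values (which also imputes missing responses under MAR),
fixed effects (matrix normal), species effects jointly (Cholesky solve
of the mk-dimensional conditional precision G⁻¹⊗A⁻¹ + R⁻¹⊗N), then G
and R from inverse-Wishart conditionals.  Two numerical choices
matter:

- **Prior.** The weakly informative inverse-gamma(0.001, 0.001) on
  each variance is implemented exactly as inverse-Wishart(Ψ = 0.002·I,
  ν = k−1+0.002): the IW marginal on a diagonal element is
  IG((ν−k+1)/2, Ψ_ii/2).  The single-response sampler uses
  IG(0.001, 0.001) directly.  A known consequence of such near-boundary
  covariance priors is that when the heritable covariance is weakly
  identified (singleton-heavy species sampling), the implied prior on
  G's correlations piles mass near ±1; with adequate within-species
  replication the data dominate.  This was verified against an
  independent random-walk Metropolis sampler on the analytically
  marginalized posterior (species effects integrated out).
- **Interweaving.** The global intercept and the mean species effect
  are strongly confounded; an ancillarity–sufficiency interweaving
  step resamples the shared location from the species-effect prior
  each sweep (valid because the likelihood is invariant under the
  shift).  This raised worst-case effective sample sizes by an order
  of magnitude at no measurable cost.

Inverse-Wishart draws use a Bartlett-decomposition sampler and the
Kronecker products are formed by broadcasting; both were profiling
targets, validated against scipy's sampler.

Diagnostics are the classic formulas: Gelman–Rubin PSRF
√(((n−1)/n·W + B/n)/W) across chains for every scalar parameter
(threshold 1.1), effective sample size from Geyer's
initial-positive-sequence autocorrelation truncation on merged chains
(threshold 200), and shortest-interval 95% HPDs.  DIC = mean deviance
+ pD with pD = mean deviance − deviance at posterior means of (B, U,
R); the deviance is conditional on species effects and marginal over
the latent measurement layer (observed ~ N(Bᵀx + u, R + diag(v))),
the MCMCglmm-style convention — a marginal-over-U deviance has no
closed form here.  DIC is reported per chain and averaged.  Model
selection first excludes any candidate containing a fixed effect whose
95% HPD intervals include zero for every response, then takes minimum
averaged DIC; differences under 0.5 are ties broken toward fewer
fixed-effect columns.

Heritability is G_ii/(G_ii+R_ii) per draw (measurement-error variance
excluded from the denominator), reported from the intercepts-only
model because covariates drain the residual and inflate the ratio.
Trait-pair correlations divide each covariance by the geometric mean
of its variances, per draw, for G (heritable), R (residual) and G+R
(phenotypic).

Default chains (2 × 6 000 iterations, 1 000 burn-in, thin 5) suit the
desk-scale problems the test-suite exercises; all counts are
configurable and production analyses should scale them up and check
the PSRF/ESS output.

## Size scaling

Single-response mixed regressions of B0^¼ (either Tref), ln Bpk or
ln B0 on ln cell volume, with species identity random on the
intercept, the slope, or both, and with or without the phylogenetic A
— a 6-model grid per response compared by DIC with the same tie rule.
R² components follow Nakagawa–Schielzeth: σ²_fixed is the variance of
the fixed-part predictor over the data, σ²_random averages zᵀGz over
the observed random-effect design (which handles random slopes), and
Rm² = σ²_fixed/total, Rc² = (σ²_fixed+σ²_random)/total.  A ln B0
response violates the Gaussian-response assumption and triggers a
logged warning, not an error.

## Environmental summaries

Drift-trajectory covariates are computed per replicate first — median
and IQR of daily temperature and latitude over the first 50/150/250/
350/500 days (or the full shorter record) — then averaged across
replicates weighted by the number of days each actually contributed.
The order is deliberate and tested: pooling days before the median
gives different answers.  Quantiles interpolate linearly between order
statistics (the numpy default).  Origin statistics are the plain
median/IQR of the location's daily SST series.

## Synthetic data: what it does and does not emulate

The generator produces exactly the structures the model assumes:
pure-birth trees scaled to unit height; species effects matrix-normal
with covariance G ⊗ A; per-TPC residuals with covariance R; optional
latitude fixed effects, known-variance measurement noise, and
missing-completely-at-random masks.  Growth curves are B(T) plus
additive Gaussian noise with sd equal to a fraction (default 5%) of
Bpk — additive so that nonpositive rates arise naturally in the cold
tail and exercise the removal rule.  Coverage plans (`full`,
`rise_only`, `sparse`) exercise the missingness flags.  TPC counts per
species default to a mixture mirroring real compilations (~56%
singletons, most of the rest 2–5).  Default parameter ranges:
E lognormal around 0.65 eV (σ 0.3), Tpk ~ N(293 K, 5 K), ED 3–6×E,
B0 lognormal around 5×10⁻⁶ s⁻¹.  Trajectories are stationary AR(1)
walks (default lag-1 correlation 0.95).

Because the generator implements the model's own assumptions, passing
recovery tests demonstrate internal consistency — correct likelihoods,
conditionals and bookkeeping — not robustness to the ways real data
violate the model (non-Gaussian trait evolution, phylogenetically
structured sampling effort, non-MAR missingness, correlated
measurement error).  Those violations are outside the package's claims.

## Known limitations

- Posterior means of heritability and of heritable correlations are
  noisy functionals of a single tree: a 60-taxon pure-birth tree has
  few independent deep splits, so per-dataset estimates legitimately
  range widely around the truth; recovery checks average over
  replicate trees.
- Under singleton-heavy sampling the heritable correlation is
  prior-dominated (see the prior note above) and biased toward ±1;
  recovery experiments therefore use replicated designs.
- The conditional-deviance DIC is not comparable with marginal-DIC
  values from other software.
- Gaussian responses only; no non-Gaussian families, no additional
  random terms beyond species.
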