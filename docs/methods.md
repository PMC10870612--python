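# Methods

## Setting and data model

A two-arm randomized trial follows each participant at occasions
`d_1 < ... < d_s` (abstract time units; internally the convention is that
one unit is the spacing that makes the schedule convenient, e.g. 3 months).
The estimand is the treatment effect `β_s` on the outcome at the primary
occasion `d_s`. Outcomes per participant are multivariate normal with
arm-by-occasion means and covariance `Σ = S^{1/2} R S^{1/2}`; participants
are independent. At an analysis time `t` the data are monotone: a
participant recruited at calendar time `a` contributes exactly the prefix of
occasions with `a + d_r ≤ t`. Missingness therefore arises only from
shortened follow-up (administrative censoring) — there is no dropout model,
and this is the single biggest idealization relative to real trials.

With `Σ` known, the GLS estimator `β̂ = (ΣX_i'Σ_i⁻¹X_i)⁻¹(ΣX_i'Σ_i⁻¹y_i)`
is the MLE with covariance `(ΣX_i'Σ_i⁻¹X_i)⁻¹`. The design matrix uses a
cell-means parameterization — `s` occasion-mean columns plus `s`
occasion-by-treatment columns — chosen because it makes `β_s` the last
coefficient and keeps the per-pattern blocks trivially sparse. Because
patterns are prefixes, participants fall into at most `2s` (arm, prefix)
groups and all sums collapse to group-level cross-products; results are
identical to the per-participant computation.

## Recruitment models

`N_r(t) = k g(t − d_r)`, clamped to `[0, g(T_R)]`, with

| model      | k                | g(u)               | rate profile            |
|------------|------------------|--------------------|-------------------------|
| fixed      | N / T_R          | u                  | constant N/T_R          |
| increasing | N / {T_R(T_R+1)} | u(u+1)             | ramps up, mean N/T_R    |
| decreasing | N / {T_R(T_R+1)} | u(2T_R − u + 1)    | front-loaded, mean N/T_R|

The `(T_R + 1)` factors stem from a per-integer-day derivation of the linear
rates; the accrual functions are nonetheless evaluated in continuous time.
The discrete/continuous discrepancy is O(1/T_R) and accepted because this
convention reproduces the reference planning quantities exactly. Expected
counts are kept real-valued internally; table renderers round for display.
The inverse lookup `time_at_tau0` solves `N_s(t)/N = τ0` in closed form
(linear or quadratic root inside `(d_s, d_s + T_R]`). Any third-party model
supplying a pair `(k, g)` with `g` non-negative, non-decreasing and
`g(0) = 0` plugs into the same machinery.

## Correlation models and the closed-form variance

Uniform (compound symmetry, parameter `α`) and exponential (AR(1)-type,
parameter `γ` = correlation at unit time separation) are supported;
`param = 1` is excluded everywhere because `R` degenerates (the limiting
variance values are available analytically instead). Both families admit
closed-form determinants and inverses — compound symmetry via the rank-one
update formula, the exponential model via its Markov property, which makes
`R⁻¹` tridiagonal in the adjacent-gap correlations `γ^{d_{r+1} − d_r}`.
These are what make `var(β_s)` explicit:

* uniform: a telescoping sum over occasions weighted by the determinant
  ratios `(1 − α)(1 + mα)/(1 + (m−1)α)`;
* exponential: a sum weighted by adjacent-gap terms
  `(1 − γ^{2Δ})γ^{2(d_s − d_r)}`.

Both reduce at `s = 2` to the familiar two-occasion formula with
`ρ = α = γ^{d_2 − d_1}`. The planning formulas involve only `σ_s`;
heterogeneous per-occasion SDs are supported in `Σ` construction because the
simulator and the GLS module need the full covariance. Exponents use the
schedule's units exactly as supplied; `FollowUpSchedule.rescaled()` divides
by `d_1` for callers working in months.

Every closed form is verified in the test suite against
`gls_variance_oracle`, an independent brute-force construction of the GLS
information matrix summed over (pattern, arm) blocks, at 1e-8 relative
tolerance on random configurations.

## Variance-reduction factor and its extrema

`V_s(t) = var(β_s(t)) / var(β_s(t) | ρ = 0)` isolates the contribution of
the early outcomes; `τ(t) = τ0(t)/V_s(t)`. For the uniform model the
extrema over the intermediate occasion times are closed-form (intermediates
collapsed onto `d_1` for the minimum, onto `d_s` for the maximum). For the
exponential model only the maximum is closed-form; the minimum trades more
data (earlier intermediates) against weaker correlation with the primary
occasion and is found numerically: SLSQP over `d_2 < ... < d_{s-1}` with an
analytic gradient (product-rule differentiation of the count-ratio and
correlation-decay factors), a minimum inter-occasion gap of 1e-6 to keep
the ordering strict, an interior start at equal spacing, and an ftol of
1e-10. The gradient is validated against central finite differences (1e-6
step) and the minimum against dense grid search (within 1e-4 for s = 3, 4)
in the tests. If the optimizer ever reports a value above the equal-spacing
evaluation, the equal-spacing point is returned instead — a cheap guard
against a poor local step.

For cross-model comparisons on a common grid the exponential parameter is
calibrated as `γ = α^{1/(d_s − d_1)}`, which equates the two models' maxima;
the planning-table grids use `d_1 = 1`, `d_s = 2`,
`d_r = 1 + (r−1)/(s−1)` and `T_R = 4·d_s` (configurable; this multiple
reproduces the reference count ratios 0.55/0.71/0.78 etc. at
τ0 = 0.15/0.30/0.45).

## Group-sequential engine

Sequential z-statistics at information levels `I_1 < ... < I_K` follow the
canonical joint distribution: `E[Z_k] = δ√I_k`,
`cov(Z_j, Z_k) = √(I_j/I_k)`. First-exit probabilities through lower
(futility) and upper (efficacy) bounds are computed by the classical
continuation-density recursion, with Gauss–Legendre quadrature (768 nodes
per analysis, grid spanning the continuation region clipped to mean ± 8 SD;
halving/doubling the node count moves probabilities by < 1e-6, and a 10⁶
draw Monte Carlo agreement test runs in the suite). Testing is one-sided
throughout: rejection is an upper exit, and at the final analysis the two
bounds coincide so exit probabilities total 1. `+inf` upper bounds encode
"no efficacy stopping at this analysis". Boundary solving from null
first-exit probabilities proceeds sequentially (analysis 1 → K) by
bracketed scalar root finding and round-trips with the forward computation
to 1e-6. Sample-size search holds the z-scale boundaries and the `τ`
schedule fixed, rescales `I_max = Nφ(1−φ)/σ_s²`, and bisects on the
integers (power is monotone in `N`).

Futility stopping probabilities under a harmful effect are computed with
the **planned** z-scale lower bounds held fixed while the realized
information varies with the first-interim timing and the assumed
correlation. This convention reproduces the published spot values for the
first interim to 3 dp. One reference value resists it: the second-interim
probability at (t₁ = 4.5, α = 0) computes to 0.530 here (confirmed by an
independent bivariate-normal CDF evaluation) against a published 0.525; the
corresponding regression test records the published value and currently
fails, deliberately — see the note in the test.

## Simulator

`simulate_trial` draws recruitment times by inverting the recruitment
model's own cumulative curve `N_0(t)/N` (uniform for the fixed model,
quadratic-root inverses for the linear models), so that simulated accrual
matches the planning formulas exactly — a requirement for the simulator to
act as the Monte Carlo oracle for them. Allocation is stratified by default
(`round(φN)` controls, randomized order) to cut Monte Carlo noise;
per-participant Bernoulli allocation is available behind a flag. Full
`s`-vectors are drawn from the multivariate normal and truncated to the
administratively observed prefix. Identical seed and spec give identical
datasets. `empirical_variance_check` fits the known-Σ GLS to each replicate
and compares the empirical variance of `β̂_s` with the closed form, using
the χ² approximation `SE(s²) ≈ s²√(2/(n−1))`.

## Covariance estimation

For monitoring realism, `estimate_covariance_ml` maximizes the profile
likelihood (mean structure profiled out by GLS) over the single correlation
parameter and per-occasion SDs, with L-BFGS-B on `[0, 0.999] × (log σ)`.
REML refinements and small-sample corrections are out of scope; the
known-Σ path is primary, and the plug-in variance understates uncertainty
when Σ is estimated — acknowledged, not corrected.

## Problem sizes and numerical defaults

The validation suite uses 200 random configurations for the closed-form vs
oracle identity, 1,000 random spacings for the extrema bracketing, 10⁶
draws for the Monte Carlo check of the exit-probability recursion, 2,000
replicates for the empirical-variance check at the exemplar first interim,
and N = 500 complete datasets for ML parameter recovery (SEs from the
observed information). Comparisons against published tables use ±0.01 for
2-dp values and one unit in the last digit for 1-dp counts and 3-dp
fractions, reflecting print rounding.

## Known limitations

* No dropout, site effects or non-normal outcomes; real accrual is noisier
  than any of the three rate models.
* The uniform model's V-minimizing spacings push intermediates toward
  `d_1`, but assuming the correlation stays fixed while occasions move is a
  strong assumption — spacing optimizations should be read as exploration,
  not prescriptions.
* Error-spending families are deliberately not first-class: boundaries or
  null crossing probabilities are the interface.
* Inference after early stopping (bias-adjusted estimates) is out of scope.
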