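# Methods

## Observation model

An individual with real lifespan `x` (age measured from the onset of
senescence) is assumed to be re-encountered at most once, at an age uniform
on `(0, x)`. The at-most-once assumption is justified for low per-occasion
recovery probability `p`: the probability of two independent recoveries is
`p²`, at most 1% for `p ≤ 0.10` (`double_recovery_probability`). The
package does not model repeated recaptures, age-dependent detectability, or
emigration; reported ages of real populations that violate these
assumptions (e.g. resighting effort concentrated in breeding seasons) are
outside the model.

Under uniform reporting the joint density of (real, reported) age is
`f_X(x)/x` on `0 < y ≤ x`, giving the marginal reported density
`f_Y(y) = ∫_y^∞ f_X(x)/x dx`. Exchanging the order of integration yields
the identity used throughout,

    s_Y(y) = ∫_y^∞ f_X(x)(x − y)/x dx = s_X(y) − y f_Y(y),

so survivorship costs one quadrature, not two; the double-integral
definition is retained as a cross-check in the test suite. Three
consequences are exact and model-free: `E[Y] = E[X]/2`; `f_Y` is strictly
decreasing; and with deaths grouped into intervals, the reported
first-interval mass is `Σ_j f_X(j)/j ≥ f_X(1)` with equality only when all
deaths fall in interval 1 (`reported_interval_fractions`), so mortality at
the onset of senescence is always overestimated.

## Real-lifespan laws

Weibull (`m(x) = m0 + (c/b)(x/b)^{c−1}`) and Gompertz–Makeham
(`m(x) = m0 + θ e^{λx}`), implemented in closed form (hazard, cumulative
hazard, survivorship, density, quantile). Defaults mirror the study
conditions analysed here: `b = 1` (the scale only changes time units),
`θ = 0.2`, curve comparisons at `c ∈ {1.25, 1.5, 2, 3}`,
`λ ∈ {0.05, 0.1, 0.2, 0.5}`, and `m0 ∈ {0, 0.2, 0.5}`. Sampling is by
inverse-CDF transform for `m0 = 0`; for `m0 > 0` hazards are additive, so a
draw is the exact competing-risks minimum of an exponential(`m0`) variate
and an `m0 = 0` draw. A single integer seed determines every draw; cohorts
record their seed, and sweep set `i` uses `base_seed + i` so any set is
reproducible in isolation.

With `c < 1` the Weibull hazard diverges at `x = 0`; hazard and density
therefore reject `x = 0` unless `c ≥ 1` (survivorship is always defined).

## Numerics

- Improper integrals over the real law are truncated at its `1 − 1e−12`
  quantile; integrands decay at least exponentially beyond it. Point
  evaluations of `f_Y` use adaptive quadrature (relative tolerance 1e−10).
- `f_Y(y) → ∞` logarithmically as `y → 0` whenever `f_X(0) > 0`, so the
  density is only evaluated at `y > 0`; curve grids start at
  `1e−3 ×` mean lifespan and are capped where real survivorship reaches
  1e−3 (200 points by default) — the range over which both hazards are
  numerically stable. The reported hazard refuses to evaluate once reported
  survivorship falls below 1e−12.
- Likelihood evaluation and distribution-level Monte-Carlo checks use a
  fast path (`ReportedLaw.tabulate`, `reported_loglik`): the integrand
  `f_X(x)/x` is tabulated on a geometric grid (3000–8193 nodes), integrated
  cumulatively from the truncation point down by the trapezoid rule, and
  interpolated at the evaluation points. Relative accuracy is ~1e−6 in the
  bulk, degrading only in the extreme tail (real survivorship below ~1e−9)
  where the absolute error remains negligible; the adaptive quadrature
  serves as its oracle in the tests.
- The mean lifespan uses the closed form `b·Γ(1 + 1/c)` (Weibull,
  `m0 = 0`) and otherwise quadrature of the survivorship truncated at the
  `1 − 1e−12` quantile.

## Estimators

*Naive* fits maximize the two-parameter real-lifespan likelihood with
`m0 ≡ 0`, matching the simulation design (data are generated with
`m0 = 0`; a three-parameter fit would be an extension, not a diagnosis of
the reporting bias). The Weibull shape solves the profile score equation
`1/c + mean(log x) − Σ x^c log x / Σ x^c = 0` by bracketed root search
(tolerance 1e−10), with the scale in closed form. The Gompertz fit profiles
out `θ = nλ/Σ(e^{λx} − 1)` and maximizes the one-dimensional profile
likelihood over `log λ` on a bounded bracket. Degenerate samples (all
observations equal) are flagged as non-converged with no estimate. Exact
zeros — probability-zero events under the continuous models — are lifted to
the smallest positive double before taking logs. Standard errors come from
the inverse observed information (central-difference Hessian at the
optimum).

The *corrected* fit maximizes `Σ log f_Y(y_i)` over the same two parameters
(log scale, Nelder–Mead, `xatol` 1e−7), each step re-tabulating `f_Y` once
on a shared grid — this is what keeps 100-set sweeps at desk scale. The
starting point is a naive fit to the doubled observations, which matches
the first moment of the real law since `E[Y] = E[X]/2`. Because
`f_X(x) = −x f_Y′(x)`, the reported density identifies the real law, and
the corrected estimator recovers `c` and `λ` to within ~1% at
`n = 10,000` (mean over 20 replicates; test suite).

## Sweeps and regression

The bias sweeps follow the study design: Weibull shapes 1.0–10.0 and
Gompertz aging rates 0.1–10.0, both in steps of 0.1 (91 and 100 sets),
10,000 individuals per set, fixed parameters `b = 1`, `θ = 0.2`, `m0 = 0`
(`θ` and `m0` for the rate sweep are carried over from the curve-comparison
conditions, as the sweep design does not restate them). Grids are built in
integer step counts so endpoints are exact. One failed set flags its row
rather than aborting the sweep. The Gompertz summary regresses fitted on
true rates by OLS *with intercept* (both conventions were considered; the
with-intercept slope is reported along with `t = slope/SE` against 0 and
the one-sided `t = (1 − slope)/SE` against 1, on `n − 2 = 98` degrees of
freedom). At full scale the slope is ≈ 0.41 and slope < 1 is rejected at
far below the 0.001 level.

The naive Weibull shape fitted to reported data has a *population* ceiling:
as the true shape `c → ∞`, reported ages approach `uniform(0, b)` scaled,
and the population score equation gives the fitted shape
`(1 + √5)/2 ≈ 1.618`; at `c = 10` the population value is 1.575. The
sweep's maximum fitted shape at `n = 10,000` therefore lands at ≈ 1.58–1.61
depending on seed — "an upper bound of approximately 1.5" in round numbers.
The sweep summary reports both the maximum and the value at the grid
endpoint, since a plotted ceiling could refer to either.

## What the simulations do and do not show

The generator produces exactly the data the observation model assumes:
i.i.d. real lifespans from the chosen law, one uniform report each, no
censoring by study span, no heterogeneity in detectability, and `m0 = 0`
in the estimation sweeps. Passing tests therefore demonstrate the internal
consistency of the bias mechanism and the corrected estimator under these
conditions — not robustness to misspecified reporting (non-uniform
resighting, study-window truncation) or to real-world heterogeneity. The
discrete first-interval result is the only claim established for arbitrary
lifespan distributions.
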