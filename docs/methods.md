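# Methods

This note documents the statistical model, the synthetic-data design, the
numerical machinery and the deliberate design choices in `deltacpue`, in the
spirit of a package methods appendix.

## 1. The two-part model

Let `c_i` be the retained count of one shark species on longline set `i`,
`h_i` the hooks set, and `y_i = 1000·c_i/h_i` the catch rate (sharks per
1,000 hooks).  Logbook catch rates of this kind are zero-inflated — roughly
a third of sets retain no sharks — and the positive part is highly
dispersed.  The delta (hurdle) decomposition treats the two features with
separate likelihoods:

**Occurrence.**  `z_i = 1{c_i > 0}` follows a Bernoulli model with logit
link,

    logit Pr(z_i = 1) = x_i' β + u_{v(i)},      u_v ~ N(0, σ_b²),

where `x_i` reference-codes year (16 levels in the full design), month (12),
fleet (foreign/local) and observer (no/unknown/yes), and `u_v` is a
per-vessel random intercept.

**Positive catch.**  Conditional on `z_i = 1`, the catch rate follows a
gamma model with log link and constant shape `k`,

    y_i | z_i=1 ~ Gamma(k, mean μ_i),   log μ_i = x_i' γ + w_{v(i)},
    w_v ~ N(0, σ_g²).

The gamma is motivated empirically: with constant shape,
`Var(y) = mean²/k`, so the slope of log cell variance on log cell mean (the
Taylor power-law exponent) is 2.  `dispersion_diagnostic` computes that
slope over year × area cells of the positive sets; values near 2 support
the gamma choice.  The two parts share no response information — the zeros
enter only the binomial likelihood, the positive magnitudes only the gamma —
which is what later justifies treating their estimates as independent when
errors are propagated.

The vessel intercepts are independent between the two parts.  No
correlation structure between them is modelled; nothing in the data the
model is designed for identifies one cleanly, and the independence
assumption is what the index's error propagation uses.

## 2. Marginal likelihood: Laplace with a quadrature audit

With one scalar random intercept per vessel, the marginal likelihood
factorizes over vessels.  For vessel `v` with log-integrand

    g_v(u) = Σ_{i∈v} log f(y_i | η_i = x_i'β + u) − u²/(2σ²) − ½log(2πσ²),

the Laplace approximation is `ℓ_v ≈ g_v(û_v) + ½log(2π) − ½log H_v`, where
`û_v` maximizes `g_v` and `H_v = −g_v''(û_v)`.  Both families have strictly
concave `g_v` in `u` (binomial: `−Σ p(1−p)`; gamma-log: `−k Σ y e^{−η}`),
so the inner Newton iteration converges globally; steps are clipped at ±5
for safety and iterated to 1e−11.

The outer optimization is quasi-Newton (L-BFGS-B) over
`(β, log σ, log k)` with fixed starting values (zeros; `log σ = log 0.5`;
`log k = 0`) and objective tolerance at the numerical floor, so fits are
deterministic.  Bounds keep `σ ∈ [1e−3, 50]` and `k ∈ [1e−3, 1e4]`; a fit
whose `σ` sits at the lower bound is numerically the fixed-effects model.
Without a random term the model reduces exactly to an ordinary GLM; that
path uses the analytic score and Hessian with a Newton polish, so the
closed-form cases (intercept-only logistic = logit of the observed
proportion; intercept-only gamma-log mean = sample mean) are reproduced to
machine precision, and the observed information gives the covariance
exactly.

For mixed fits the covariance is the inverse of a central-difference Hessian
of the Laplace objective at the optimum (relative step 1e−4), and
coefficient standard errors are taken from the fixed-effect block of the
full inverse — i.e. they carry the uncertainty in `σ` and `k`.

Because the Laplace approximation is an approximation, the package ships its
own auditor: `marginal_loglik_oracle` integrates each vessel's likelihood by
adaptive Gauss–Hermite quadrature (nodes centered at the mode, scaled by
`H_v^{−1/2}`, log-sum-exp accumulation).  It refuses instances with more
than 20 vessels — it is a test oracle, not a fitting engine.  On instances
of ≤10 vessels the two likelihoods agree to well under 1e−3 per observation
(typically ~1e−5 with 50-set vessels).

**Model selection.**  Year and the vessel intercept are always retained
(year is the quantity of interest; vessel is a known nuisance).  The
remaining terms (month, fleet, observer) enter by forward selection: at each
step the term lowering BIC most is added, stopping when no addition lowers
BIC.  BIC counts *all* estimated parameters, including `log σ` and `log k`.
Non-converged candidate fits are excluded from the comparison but recorded
in the selection table.  Error structure and links are fixed at
binomial-logit and gamma-log; the selection search covers fixed terms only.

## 3. The standardized index

For each year the linear predictor of each submodel is formed under a
prediction policy and back-transformed:

* **reference** (default): all non-year factors at their reference level
  (year 2000, January, foreign fleet, observer absent), random intercept 0.
  The link-scale variance is the quadratic form of the prediction vector in
  the coefficient covariance.
* **population**: predictions averaged on the response scale over the
  observed covariate rows, with the delta-method gradient averaged the same
  way.  Use this when fleets/seasons shift over time and a
  population-averaged trend is wanted.

Back-transformation uses the first-order delta method: `p = logit⁻¹(c)`
with `se_p = se·p(1−p)`; `μ = exp(c)` with `se_μ = se·μ`.  A lognormal
bias-corrected point estimate `exp(c + se²/2)` is available behind
`bias_correct=True`; it is off by default — the plain transform is the more
conservative, assumption-light choice.

The index is `I = p·μ` with `se_I = sqrt(μ²se_p² + p²se_μ²)`
(independence across parts, see §1).  Monte-Carlo checks in the test suite
confirm both transforms and the product rule to within 10% of simulation
SDs in the moderate-uncertainty regime (`se/estimate ≤ 0.3`); beyond that
regime first-order delta methods degrade, as expected.

Anomaly flagging is deliberately crude and post hoc: year `t` is flagged
when `I(t)/I(t−1)` or its inverse exceeds a threshold (default 3, with a
tiny floor to survive near-zero indices).  The threshold is an artifact
default — in the fishery this package emulates, order-of-magnitude
increments (e.g. a blue-shark index jumping from 4 to 191 sharks/1,000
hooks in one year) reflect retention and reporting behaviour, not
population dynamics, and the flag marks them for narrative interpretation.

## 4. Cleaning and stratification

Cleaning retains a record only if: no required field is missing; year in
2000–2015; position inside the configured study box; hooks in 310–3,800
(inclusive); per-species counts ≤ 801 (inclusive; a combined-cap variant is
available by config since the cap's per-species vs combined reading is
ambiguous); and combined sharks strictly fewer than hooks.  A record
failing several rules is tallied once under the first failing rule in the
fixed order missing → year → position → hooks → count cap → sharks-vs-hooks,
so reports are deterministic and `retained + Σ tallies = input`.  Anomalies
in fields not modelled downstream (depth, set duration, weight mismatches)
are represented by the missing-field rule.

Stratification assigns four areas from position: west of 20°E the split is
at 33°S (West above, Southwest below); east of 20°E the split is at 26°E
(South west of it, East beyond, up to the Mozambique-border latitude).  All
edges are half-open on the eastern/southern side, so 20°E and 26°E points
fall east — a pure tie-breaking convention.  The northern clips (−28.6°,
−26.85°) stand in for national-border latitudes that have no exact analytic
value; only region membership affects the analysis, and both are
configurable.  ICCAT/IOTC membership is determined by the 20°E split and is
consistent with the area map by construction.

## 5. The synthetic logbook generator

The generator draws each set's fleet, vessel, date, position, effort and
observer status, then simulates both species through the exact model of §1:
Bernoulli encounter from the binomial predictor, gamma catch rate from the
gamma predictor, counts back-derived as `round(y·h/1000)` and coerced to ≥1
on encounter (a retained-count logbook cannot show an encounter with zero
retained animals).  Key structural defaults mirror the fishery emulated:

| quantity | default | basis |
| --- | --- | --- |
| hooks per line, foreign | truncated normal, mean 2,493, SD 597 on [310, 3,800] | reported fleet effort statistics |
| hooks per line, local | truncated normal, mean 1,282, SD 250 | reported fleet effort statistics |
| fleet sizes | 61 local, 49 foreign vessels | reported fleet sizes |
| share of local sets | 0.58 | 16,810 of 29,018 sets |
| zero-catch fraction | ~30–40% via binomial intercepts | reported zero rates |
| observer coverage | foreign ~90% "yes" from 2002; mixed local; "unknown" a third level | observer-programme history |
| vessel SDs | 0.5 / 0.4 (logit), 0.4 / 0.35 (log) | plausible magnitudes |
| gamma shape | 1.0 (blue), 1.5 (mako) | strongly dispersed positives |

Year/month/fleet/observer effect magnitudes are plausible rather than
estimated (the source logbooks are confidential): catch rates step up from
2004, blue sharks are encountered more often by the foreign fleet but
retained in far greater numbers by local vessels, makos show the opposite
fleet pattern, and reported presence/magnitude drop under observation.
Positions are uniform within per-area bounding boxes so area assignment has
known truth; hooks are truncated to the cleaning range so uncorrupted
records pass the effort filter by construction.

A contamination step corrupts disjoint record fractions in six classes
(position, year, hooks, count cap, sharks ≥ hooks, missing field), returning
the corrupted ids — the cleaning tests' oracle.

What the generator does *not* emulate: time-varying discarding and
under-reporting behaviour, oceanographic drivers, spatial autocorrelation
within areas, vessel-level trends, or shark size structure.  Passing
recovery tests therefore demonstrate that the estimation machinery is
correct under the model's own assumptions — not that real logbook indices
are unbiased, which reporting behaviour can and does break.

## 6. Simulation experiment sizes

Validation experiments run at a scale chosen to give informative Monte-Carlo
precision on a single CPU: recovery uses 50 replicates of 5,000 sets and 30
vessels with a 4-year × 4-month × fleet × observer design (10 fixed
coefficients — every term type exercised, kept small so 100 mixed fits stay
cheap); the full 16 × 12 design runs end-to-end in the pipeline tests; BIC
consistency uses 20 replicates; the dispersion check uses 30 cells of ~200
positives with shape 2.  Replicate seeds are consecutive integers from a
fixed base.

Observed behaviour at these sizes: index recovery well above the 90% target
(≈97% of year-cells within 2 propagated SEs), dispersion slope ≈ 2.0,
selection includes a strong fleet effect and excludes a null observer effect
in ≥90% of replicates.  Wald coverage of true coefficients sits slightly
below nominal (≈0.91–0.95 across coefficients) — the familiar small-cluster
property of ML-Laplace mixed models: with 30 vessels, variance components
are estimated with little information and between-vessel contrasts
(intercept, fleet) have mildly anticonservative normal-theory intervals.
The same experiment with 150 vessels restores ≈0.95 coverage, confirming the
machinery is calibrated and the shortfall is the method's finite-cluster
behaviour, not an implementation defect.

## 7. Numerical details and degenerate inputs

* Linear predictors are clipped at ±500 inside likelihood evaluations to
  guard `exp` overflow far from any optimum; no fitted model approaches the
  clip.
* `σ = 0` in the quadrature oracle returns the independent-observation
  likelihood exactly; a mixed fit on σ=0 data drives `log σ` to its bound
  and reproduces fixed-effects coefficients to <1e−4.
* Possible separation in the binomial part (|coefficient| > 15) attaches a
  warning rather than failing; non-convergence is flagged
  (`converged=False`) and such fits are excluded from BIC comparison and
  refused by the index builder — never silently used.
* Empty cleaning input reports a retained fraction of 0 by convention.
* Rank-deficient designs (confounded factors) are rejected with an error
  naming the terms rather than silently dropped.
* An area × species stratum with too few positive sets (default < 30), a
  single vessel, or a single observed year yields an explicit
  "insufficient data" status instead of a fragile fit.
* The gamma submodel refuses any non-positive response: the hurdle contract
  is that zeros never reach it.

## 8. Known limitations

* The gamma part models CPUE directly, matching the index's units; a
  counts-with-log-effort-offset formulation is a defensible alternative not
  implemented here.
* Count discretization (rounding and the ≥1 coercion) injects small
  non-gamma noise at low expected counts; at the default effort levels its
  effect on estimates is negligible but it slightly inflates the estimated
  shape.
* Wald intervals for between-vessel contrasts are mildly anticonservative
  with few vessels (§6); profile or bootstrap intervals would be the remedy
  if those contrasts were the inferential target.
* Error propagation ignores any dependence between the two submodels'
  estimates; they share covariates, and with strong vessel effects their
  sampling errors are not exactly orthogonal.
* Anomaly flagging is a screening device; the threshold has no inferential
  calibration.
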