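# Methods

## The self-matched design and its likelihood

Each analysis unit is one mother. Her loss pregnancy of the target class
(stillbirth by default: terminated at gestational month ≥ 7; early
stillbirth 5–6; miscarriage < 5) is the case; her livebirths are the
controls. Only the most recent target-class loss per mother is used, the
convention for limiting recall bias in retrospective histories; mothers
without a case or without a control are dropped and counted in the
selection log.

The outcome model is `Logit(p_it) = x_it β (or f(x_it)) + z_it' γ + θ_i`
with a per-mother intercept `θ_i` capturing everything time-invariant
(genetics, residence, climate, socioeconomic baseline). `θ_i` is never
estimated. Conditioning each set on "exactly one case among these
members" yields the conditional-logit likelihood

    log L = Σ_sets [ η_case − log Σ_j exp(η_j) ],

in which any within-set constant — `θ_i` included — cancels identically.
This cancellation is the central modeling identity of the package and is
tested directly (per-set constant shifts leave the likelihood unchanged
to 1e-9; the likelihood equals brute-force enumeration on small sets to
1e-10; the fit matches an independent conditional-logit implementation
to 1e-5).

**Exposure definition.** All members of a set use a hazard time window
of the same length — the case's gestational month — each starting at the
member's *own* conception month. The exposure is the arithmetic mean of
monthly PM2.5 over that window ("gestation-adjusted PM2.5"). Equal
window lengths are what make exposures comparable within a set; without
them, longer gestations would mechanically average more months. Controls
whose own gestation was shorter than the case window keep the case-length
window (the matching rule is on length, not on the control's gestation)
and are counted in the selection log. Monthly resolution is used
throughout; no partial-month weighting.

**Covariates.** Longitudinal terms only, since spatial/time-invariant
confounding is absorbed by conditioning: natural cubic spline of
maternal age (3 DF), parity (nulliparous/multiparous), natural spline of
window-mean temperature (3 DF), natural spline of conception month
(4 DF) for seasonality, and nightlight (the conception year's annual
value) as a development indicator. Country heterogeneity — country-
specific calendar trends and country-specific PM2.5 slopes — is
available as ridge-penalized interaction columns (penalty configurable,
default 1.0; off by default). A true random-effects conditional logit is
not uniquely defined for this design, so the penalized-column
formulation is surfaced as configuration rather than presented as the
single correct choice.

**Optimization and inference.** Newton–Raphson with analytic gradient
`X'(y − p)` and observed information `X'diag(p)X − M'M`, step-halving,
convergence at gradient inf-norm < 1e-6. The unpenalized conditional-
logit log-likelihood is concave, so the optimum is start-independent
(tested to 1e-6). Coefficient covariance is the inverse observed
information; curve confidence bands are pointwise Wald (delta method) on
the basis expansion. Columns constant within every set are inestimable
under conditioning and are dropped with a log message; remaining
collinearity raises an error naming the offending columns. Fitting
requires ≥ 30 sets by default.

## Splines and exposure–response functions

One-dimensional smooth exposure terms are natural (restricted) cubic
splines with `df + 1` knots at equally spaced quantiles including the
observed extremes; they are unpenalized, for exact reproducibility of
fits from (knots, coefficients) alone. In one dimension, thin-plate and
cubic smoothing splines span the same function space up to basis choice,
so a fixed-DF natural cubic basis is the reproducible representative of
that family. The basis is hand-implemented (rather than taken from a
formula library) so that fitted curves serialize to JSON and evaluate
identically inside and outside the fitting code; natural-spline tails
are linear, which also defines the extrapolation behavior.

An ERF stores form (log-linear or spline), reference concentration C0,
coefficients, coefficient covariance, age group, and the fitted exposure
range. Evaluation applies the positive part first, `f(max(C − C0, 0))`,
and is exactly zero at and below C0 by a difference-basis construction
`B(C) − B(C0)` — every Monte Carlo draw of the coefficients is therefore
anchored too, and the pointwise CI has zero width at C0. Evaluation
outside the fitted range is flagged as extrapolation in the returned
metadata (low-end extrapolation in particular is unreliable: the curves
are estimated where the data are, and the fitting samples here contain
no very clean-air observations).

Age-specific curves come from a single model with exposure-basis ×
age-group interactions and *shared* covariate coefficients; per-stratum
curves are then extracted with their joint covariance. One shared fit
keeps the covariate adjustment common across strata and yields the joint
coefficient covariance needed to sample all four curves coherently in
the Monte Carlo step. (Whether the original analyses shared covariates
across strata is not documented; the joint fit is this package's design
choice.)

Two published log-linear pooled estimates ship as presets
(`zhang2021`: OR 1.103, 95% CI 1.074–1.131 per 10 µg/m³; `xie2021`:
OR 1.15, 95% CI 1.07–1.25), with β = ln(OR)/10 and the log-scale SE
back-solved from the CI half-width. Note the xie2021 interval is not
log-symmetric around its point estimate, so normal draws reproduce the
closed-form transform of β's CI, not the printed bounds, exactly.

## Population at risk and burden attribution

Gridded total pregnancies `P_s` (one reference year; weights are held
constant across assessment years, matching the practice of freezing the
pregnancy grid to its single available year) are split by maternal age
via expected births: `P_sk ∝ W_sk R_ik` within pixel, normalized to
conserve `P_s` (asserted to 1e-9 relative). Five-year bands (10–54) are
split first, then aggregated to the four analysis groups. The
pixel→country map is an input column; no GIS operations are performed.
Pixels with neither pregnancies nor expected births contribute zero and
are counted; zero expected births with positive pregnancies is an error.

Exposure is the pregnancy-weighted mean concentration (overall or per
age group, country or domain level). Attributable fractions use
`AF = 1 − exp(−f_k(Δ))` per pixel and group, pregnancy-weighted to
country level; `AN = AF × N`. Spline curves can dip below zero at some
excess concentrations; negative (protective) pixel AFs are reported as
computed by default, with a count in the log, and a clamp-at-zero option
exists — the choice is surfaced because no single convention is
standard.

**Monte Carlo intervals** propagate exactly two uncertainty sources:
curve coefficients (multivariate normal from the estimation covariance;
jointly across age groups when the curves come from one fit) and the
baseline stillbirth totals `N_iy` (lognormal with μ = ln(point) and σ
solved from the 95% CI half-width on the log scale — counts are positive
and reported intervals are asymmetric, which the lognormal respects).
Curve and baseline draws are independent. Exposure-field uncertainty is
deliberately excluded. Intervals are 2.5th/97.5th percentiles over
`n_draws` (default 1,000; the closed-form calibration test uses 10,000),
deterministic under a fixed seed.

**Scenarios** cap the concentration field at a WHO target,
`C' = min(C, target)`; avoided burden is baseline AN minus counterfactual
AN. Capping at or below C0 removes all excess burden by construction.

**Trends** are annual percent declines, either geometric from the two
endpoints, `100·(1 − (V_end/V_start)^(1/(y1−y0)))`, or from a log-linear
regression of the yearly series. Both are provided because published
decade rates are not always consistent with the endpoint formula applied
to the published totals (e.g., a reported 2.05%/yr for 2010–2019 against
~1.98%/yr from the printed endpoint values suggests a regression-based
rate); the package documents the two definitions rather than guessing
which produced a given published number.

## The synthetic-data generator

The generator emulates the *analysis sample* of a multi-country,
survey-based self-matched study — mothers with several pregnancies and a
substantial share of losses — not general-population loss rates. Its
outcome mechanism is exactly the estimator's assumed model: each mother
draws a Normal(0, σ²) intercept (σ = 0.75 by default; the distribution
is irrelevant to the estimator since conditioning removes it), one loss
gestational length G from a categorical over months 2–9, and per
pregnancy a Bernoulli outcome with log-odds = baseline + θ_i +
f_true(x)·age-modifier + covariate effects, where x is the mean PM2.5
over G months from that pregnancy's own conception. Losses get
gestation G (classifying them as stillbirth/early stillbirth/
miscarriage); other pregnancies are livebirths at 9 months.

Key defaults and why:

- **PM2.5**: country means drawn from 12–75 µg/m³ (between-country SD
  comparable to the ~22 µg/m³ overall SD typical of multi-country LMIC
  exposure data), sinusoidal seasonality of amplitude 15 µg/m³, and
  stationary AR(1) monthly noise (marginal SD 14, ρ = 0.4), truncated at
  zero. Monthly swings of this size are realistic for high-exposure
  settings and give within-mother exposure contrasts.
- **Family structure**: 2–8 pregnancies per mother (2 + geometric,
  p = 0.3), conceptions ≥ 10 months apart; loss gestational length
  weighted toward ≥ 7 months (P = 0.75) so the primary stillbirth
  analysis retains most mothers while all four outcome classes occur.
- **Baseline log-odds −1.2**, giving a ~30% per-pregnancy loss share —
  the case share such designs exhibit *within the analysis set* (the
  design samples mothers with a loss).
- Together these make a 10,000-mother simulation yield ~5,000 stillbirth
  matched sets whose fitted SE(β) ≈ 0.0026 per µg/m³, comparable to the
  precision of the survey analyses this emulates (implied SE ≈ 0.0021).
  These are the study conditions for the parameter-recovery tests, fixed
  by this design target.
- **True curve**: log-linear OR 1.11 per 10 µg/m³ by default, with an
  optional concave ("sublinear") form a·ln(1 + x/s) and multiplicative
  age modifiers for effect-modification experiments.
- **Risk grid**: 250 pixels by default across the configured countries;
  pregnancies allocated by expected-birth shares to an exact configured
  total; country stillbirth totals declining 2%/yr with lognormal-style
  95% CIs.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: spatial autocorrelation of PM2.5
fields, survey design weights, residential mobility during pregnancy,
outcome underreporting and misclassification, gestational-age recall
error, and time-varying confounders such as antenatal care. Parameter
recovery here shows the estimator is correct under its assumed model,
not that the assumptions hold in any particular survey.

One generator subtlety: with multiple losses per mother, only the most
recent enters the analysis (matching the eligibility rule). Because the
simulated exposure process is stationary, which loss is "most recent" is
uninformative about exposure, and recovery simulations across seeds show
no detectable bias (mean z ≈ 0.02 over 30 replicates at study scale).
Under a strong secular exposure trend this selection could matter; the
trend knobs exist to explore that.

## Numerical choices and degenerate inputs

- Likelihood and softmax use per-set max subtraction; no overflow for
  any finite linear predictor.
- Knot placement requires strictly increasing quantiles; degenerate
  (near-constant) inputs raise rather than silently producing a singular
  basis.
- Disaggregation conservation is asserted to 1e-9 relative at pixel
  level; exceedance uses strict inequality (`C > threshold`).
- Ties/ordering: matched-set tables are sorted by set id; member order
  within a set never affects exposures, likelihood values, or fits
  (tested by shuffling).
- Reference levels: named WHO constants or `custom:<value>`; named and
  numerically identical custom levels give identical results.
- Monte Carlo sampling uses SVD-based multivariate normal draws, so
  exactly singular covariances (including all-zero) are handled; a zero
  covariance yields degenerate (zero-width) intervals.
- All generator draws derive from `numpy.random.default_rng` seeded as
  `[seed, stream]`, so the three generator entry points are mutually
  independent but individually reproducible; identical config + seed
  gives byte-identical CSV output.

## Known limitations

- The "random effects" for country heterogeneity are ridge-penalized
  fixed-effect columns, not integrated random effects.
- Wald bands are asymptotic: at a few hundred sets they undercover
  modestly (observed sd(z) ≈ 1.1 in small-sample experiments); coverage
  statements hold at study scale (thousands of sets).
- Spline ERFs extrapolate linearly outside the fitted exposure range and
  can produce large or negative attributable fractions there; the
  extrapolation flag should be honored when the assessment grid is wider
  than the fitting sample's exposure support.
- Assessments are annual and country-level; no sub-annual burden, no
  PM2.5 composition (e.g., dust) differentiation, no reprojection of
  mismatched grids.
- `AN = AF × N` treats the baseline total as exchangeable with the
  age-aggregated AF; age-resolved baselines are not modeled.
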