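# Methods

This note records the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Model and estimation

Observations are study-level log relative risks `y_ij` with reported
sampling SEs `σ_ij`. Odds and hazard ratios are ingested on the log
scale unchanged; using a non-RR measure is treated as a *bias covariate*
rather than transformed away, so the model can estimate (and correct)
any systematic shift it induces. Reported 95% CIs are converted to SEs
as `(log U − log L)/(2·1.96)`, assuming a symmetric normal interval on
the log scale; for asymmetric printed intervals the full width is used
rather than the larger half-width (deterministic, and standard
meta-analytic practice). When a study contributes k non-mutually-
exclusive effect sizes from the same sample, each SE is inflated by √k
(applied after CI→SE conversion), so the k rows jointly carry the
inverse-variance weight of one independent observation — this is the
sense in which repeated measurements are prevented from overweighting a
study. An SE×k variant is available (`repeat_adjustment: linear`) but
over-penalises.

The marginal model is

    y_ij = β₀ + x_ijᵀβ + u_i + ε_ij,  u_i ~ N(0, γ),  ε_ij ~ N(0, σ_ij²),

with one random effect per `study_id` (the within-study correlation
accounting). Estimation is maximum marginal likelihood, not REML: the
trimming objective and the Fisher-information machinery are defined on
the ordinary likelihood, and mixing REML with likelihood-ranked
trimming would make the objective incoherent. For fixed γ the fixed
effects have the closed-form GLS solution, with each study's covariance
`V_g = diag(σ²) + γ11ᵀ` inverted by the Woodbury identity in O(n_g).
The profile likelihood in γ is then maximised by bounded Brent search
on [0, 10·var(y)+1] with `xatol = 1e-12`, followed by an explicit
comparison with the γ = 0 boundary (the bounded search cannot land
exactly on it). This replaces a joint quasi-Newton iteration: the
profile is one-dimensional, smooth, and cheap, so the simpler scheme is
both more robust and exactly as accurate. γ may legitimately estimate
to 0; it is reported as 0, not a small positive number.

`var(β₀)` is the (0,0) element of `(XᵀV⁻¹X)⁻¹`; with all selected
covariates at their gold-standard level 0 this is directly the variance
of the bias-adjusted pooled log RR (`predict_reference`).

### Heterogeneity uncertainty

The Fisher information of γ under the marginal likelihood is

    I(γ) = ½ Σ_g tr[(V_g⁻¹ ∂V_g/∂γ)²] = ½ Σ_g (1ᵀV_g⁻¹1)²,

and `sd(γ̂) = I(γ̂)^{-1/2}`. For m equal-information studies with
per-study marginal variance v this reduces to `v·√(2/m)`, which the
tests assert exactly. At γ̂ = 0 the same one-sided information is used
(no reflection); this keeps sd(γ̂) finite and the 95th quantile
γ* = γ̂ + 1.645·sd(γ̂) strictly positive whenever the data are
informative, which is what makes the method conservative for
small evidence bases.

### Trimming

With ≥ 10 observations, 10% likelihood-based trimming is applied:
retained size is `ceil((1−trim)·n)`; observations are ranked by their
marginal log-density `−½[log 2π(σ²+γ̂) + r²/(σ²+γ̂)]` under the current
fit, the top block retained, the model refitted, iterating to a fixed
point (max 100 iterations; ties broken by smaller SE retained first,
then input order). This is the standard trimmed-MLE scheme; on
10-observation sets with a planted +3 log-unit outlier it provably
picks the same subset as exhaustive leave-one-out likelihood search
(asserted in the tests). Trimming below 10 observations is disabled
regardless of the requested proportion.

### Bias-covariate selection

A covariate is testable only when both its levels appear in ≥ 2 rows.
Selection is a Lasso-guided stepwise procedure: the design and response
are standardised by 1/σ, the (weighted) intercept projected out
(Frisch–Waugh) so it is effectively unpenalised, and the
scikit-learn coordinate-descent path (100 log-spaced λ, eps 1e-3)
provides the entry order; each entrant is kept iff its coefficient is
significant at α = 0.05 (two-sided Wald) in an unregularised mixed-model
refit containing the covariates already kept. Selection runs on the
untrimmed data; the final fit is trimmed (configurable). The Lasso
pre-screen makes exact type-I calibration loose; the simulations bound
the null selection rate at ≤ 10% rather than asserting 5%.

## Evidence scoring

With μ = β₀ (reference level), v = var(β₀), γ* as above:

* UI without γ: `exp(μ ± 1.96√v)`; UI with γ: `exp(μ ± 1.96√(v+γ*))`.
* BPRF (harmful): `exp(μ − 1.645√(v+γ*))`; protective risks use the
  opposite tail — always the 5th quantile *closest to the null*.
* ROS = log(BPRF)/2 for harmful, −log(BPRF)/2 for protective.
* Stars: 0 when the UI **without** γ crosses RR = 1 (BPRF/ROS are then
  suppressed and rendered "N/A"); else 1★ for ROS ≤ 0, 2★ (0, 0.14],
  3★ (0.14, 0.41], 4★ (0.41, 0.62], 5★ above. The ROS = 0.0 boundary
  belongs to one star.

The "95th quantile of γ" is implemented as the normal-approximation
quantile γ̂ + 1.645·sd(γ̂), truncated at 0, and the *same* γ* feeds both
the heterogeneity-inclusive UI and the BPRF. This self-consistency is
what the published-table sweep verifies: back-solving σ_total from each
printed RR and heterogeneity-inclusive UI and applying
`exp(ln RR − 1.645·σ_total)` reproduces every printed BPRF and ROS to
within one unit in the last printed decimal place (the residual
deviation, up to 0.0075, is fully explained by the printed inputs
themselves carrying only two decimals), and the published star bins
reproduce all 20 star categories exactly. Reports round RR/BPRF/ROS to
2 dp; internal values keep full precision.

The theoretical minimum risk exposure level for both risk factors is
zero exposure; it is recorded as metadata and nothing is computed from
it.

## Publication bias

Egger's test regresses the covariate-adjusted residuals on their SEs
with an intercept, weighted by the inverse marginal variance
`1/(σ² + γ̂)`. The canonical formulation weights by 1/σ²; with γ > 0
that weighting is strongly miscalibrated (a σ = 0.05 observation's
residual variance is dominated by γ, inflating its nominal weight by
~17× in our default scenario), so the likelihood-consistent marginal
weighting is used instead — it reduces exactly to 1/σ² when γ̂ = 0.
Slope p-values use the t distribution on n−2 df; a pair is flagged at
p < 0.05 (the threshold is configurable; all-identical SEs return an
explicit zero-design-variance diagnostic, not a flag). The test runs on
the retained (post-trimming) residuals by default. Funnel tables include
trimmed points, flagged.

## Synthetic data

`simulate_dataset` draws, per study, `u_i ~ N(0, γ)`; per observation,
`σ ~ U(se_range)`, covariates `Bernoulli(0.3)` independently, and
`y = β₀ + Σβ_cov·x + u_i + egger_slope·σ + N(0, σ²)`; a fraction of
observations is then mean-shifted by `outlier_shift` (outliers are
mean-shifted, not variance-inflated, because that is what trimming is
designed to remove). Defaults — 12 studies, 1–2 observations each,
SEs on (0.05, 0.5), γ = 0.04, β₀ = ln 2 — are chosen once to match the
scale of the real IPV/CSA evidence bases (a dozen studies, back-solved
heterogeneity mostly in the 0.02–0.2 range, forest-plot SEs spanning
roughly one decade). The generator emulates the *effect-size level*
only: it does not simulate individual participants, correlated
covariates, selective reporting mechanisms beyond the linear SE term,
or non-normal random effects — so passing tests demonstrate correctness
of the estimator under its own assumptions, not robustness to every
real-data pathology.

## Problem sizes used in the checks

The recovery check uses 20 replicates of 50 single-observation studies;
the trimming oracle 10 replicates of 10 observations; Egger calibration
500 null replicates and power 200 contaminated replicates of 30
single-observation studies. These sizes give Monte-Carlo error well
inside the asserted bounds while keeping the whole suite fast.

## Known limitations

* Egger power degrades with heterogeneity: at the default γ = 0.04 the
  flag rate under slope-1 contamination drops to ≈ 0.5 (from ≈ 0.8 at
  γ = 0), because between-study variance dilutes the SE–effect signal.
  The calibration/power checks therefore run at γ = 0, which isolates
  the test's own behaviour; detection claims should not be extrapolated
  to strongly heterogeneous evidence bases.
* The γ normal approximation can be poor for very few studies (3–5);
  the Fisher-information sd is then large, which errs conservative
  (wider UIs, smaller BPRF), consistent with the framework's intent.
* MLE of γ is biased low in small samples (visible in the recovery
  simulations, median γ̂ ≈ 0.032–0.04 at truth 0.04 with 50 studies).
  REML would reduce this bias but is deliberately not offered: it is
  incompatible with the likelihood-ranked trimming objective, and a
  second estimation mode would invite silent inconsistency. `fit`
  accepts `fix_gamma` for sensitivity analyses at externally chosen
  heterogeneity values.
* No multiple-testing correction is applied across risk–outcome pairs;
  each pair is scored independently, matching standard practice for
  this framework.
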