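# burdenproof

Burden-of-proof evidence scoring for dichotomous risk factors.

`burdenproof` is for epidemiologists and meta-analysts who need a
conservative, heterogeneity-aware answer to the question *"how strong is
the evidence that exposure X raises the risk of outcome Y?"* given a set
of published study-level relative risks. It implements the
burden-of-proof evidence pipeline for binary (exposed / unexposed) risk
factors — the framework used to score associations such as intimate
partner violence with major depressive disorder, or childhood sexual
abuse with alcohol use disorders — from extraction table to star rating.

## The model

Each extracted effect size is carried on the natural-log scale. For
observation *j* of study *i*,

    y_ij = β₀ + x_ijᵀβ + u_i + ε_ij,
    u_i ~ N(0, γ),    ε_ij ~ N(0, σ_ij²),

where `y_ij` is the reported log relative risk, `σ_ij` its sampling
standard error (inflated by √k when k non-independent effect sizes share
one sample), `x_ij` binary bias covariates marking departures from the
gold-standard design (odds ratio reported, non-representative sample,
uncontrolled confounding, …), `u_i` a study-level random effect inducing
within-study correlation, and `γ ≥ 0` the between-study heterogeneity
variance.

The pipeline, per risk–outcome pair (requiring ≥ 3 studies):

1. **Bias-covariate selection** — candidates testable with ≥ 2 rows per
   level enter in L1-regularisation-path order and are kept when a
   Wald test in the unregularised mixed refit is significant at 0.05.
2. **Trimmed maximum-likelihood fit** — with ≥ 10 observations, the 10%
   of observations least consistent with the fit are removed by
   iterative likelihood-based trimming; β is profiled out by GLS and γ
   maximised on [0, ∞). The uncertainty of γ̂ comes from the Fisher
   information, I(γ) = ½ Σ_g (1ᵀV_g⁻¹1)².
3. **Uncertainty intervals** — a 95% UI from the fixed-effect variance
   alone, and a conservative UI adding γ at its own 95th quantile,
   γ* = γ̂ + 1.645·sd(γ̂).
4. **Burden-of-proof risk function (BPRF)** — the 5th-quantile estimate
   of the RR closest to the null, inclusive of heterogeneity: for a
   harmful risk `exp(β₀ − 1.645·√(var(β₀) + γ*))`, i.e. the most
   conservative relative risk consistent with the data.
5. **Risk–outcome score and stars** — ROS = log(BPRF)/2 (signed so that
   positive means evidence of association), binned into 1–5 stars
   (≤ 0 → 1★, (0, 0.14] → 2★, (0.14, 0.41] → 3★, (0.41, 0.62] → 4★,
   > 0.62 → 5★). A pair whose *no-heterogeneity* UI crosses RR = 1 is
   rated 0 stars and BPRF/ROS are not reported.
6. **Publication bias** — Egger's regression of the fitted residuals on
   their standard errors (inverse-marginal-variance weighted), flagged
   at p < 0.05, plus funnel-plot data.

A synthetic-data generator (`SyntheticTruth`, `simulate_dataset`)
produces evidence bases with exactly this generative structure — study
random effects, bias-covariate shifts, mean-shifted outliers, optional
SE–effect dependence for publication-bias scenarios — with the ground
truth returned alongside, so every stage is testable without any
external data.

## Worked example

```python
import math
from burdenproof import SyntheticTruth, simulate_dataset, run_pair

truth = SyntheticTruth(beta0=math.log(2.1), gamma=0.019, n_studies=12, seed=4)
dataset, truth = simulate_dataset(truth)
result = run_pair(dataset)

print(result.fit.summary())
s = result.score
print(f"RR {s.rr:.2f}  BPRF {s.bprf:.2f}  ROS {s.ros:.2f}  stars {s.stars}")
```

prints

```
Mixed-effects meta-regression (log relative risk)
====================================================
risk / outcome        : synthetic_risk / synthetic_outcome
observations retained : 18 / 20
studies               : 12
log-likelihood        : -2.141777
gamma (between-study) : 0.016962 (sd 0.018912)

term                                coef          se         z
intercept                       0.717841    0.065134    11.021

RR 2.05  BPRF 1.41  ROS 0.17  stars 3
```

The evidence base was generated with a true pooled RR of 2.1 across 12
studies and modest heterogeneity. The fit retains 18 of 20 observations
after 10% trimming and estimates a pooled RR of 2.05. The BPRF of 1.41
says the data conservatively support *at least* a 41% risk increase once
between-study heterogeneity is charged against the estimate; ROS 0.17
falls in the (0.14, 0.41] bin, a three-star (moderate-evidence) rating —
matching the published rating for evidence bases of this strength.

The same pipeline is available from the shell:

```
burdenproof simulate --seed 4 --n-studies 12 --beta0 0.742 --gamma 0.019 --out sim/
burdenproof score --input sim/observations.csv
burdenproof sensitivity --input sim/observations.csv --no-trim
```

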