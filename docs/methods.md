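# Methods

## Model structure

`oncopop` treats a virtual patient as the output of a directed acyclic
simulation network. Five primary variables are sampled first and are only
ever used as predictors:

* **tumor type** — nine categories (breast, colon, endometrial, gastric,
  hepatic, lung, ovarian, pancreatic, sarcoma);
* **sex** — conditional on tumor type; the probability of male given each
  tumor defaults to the source cohort's observed ratios (e.g. 513/865 for
  lung, 43/66 for pancreatic) and is structurally zero for breast,
  endometrial and ovarian cancer;
* **biogeographic origin** and **ECOG performance status (0–2)** —
  independent multinomials;
* **age** — Weibull with four (sex × sarcoma) parameter groups, truncated
  to [18, 95] years.

Ten secondary variables are then generated in a fixed order, each a linear
model on primaries and strictly earlier secondaries plus Gaussian noise on
the modeled scale. Six stages are modeled on the natural-log scale (weight,
AAG, N-L ratio, P-L ratio, CRP, LDH) and back-transformed by
exponentiation, which guarantees positivity; the log base is the natural
log, fixed by checking that exponentiated intercepts are physiologic
(e^4.32 ≈ 75 mg/dL AAG, e^5.709 ≈ 302 U/L LDH). Covariate scales are mixed
exactly as published: the N-L stage consumes *log* AAG while the P-L stage
consumes raw AAG (mg/dL) and the raw N-L ratio, and the LDH stage consumes
raw CRP. BSA (Mosteller, √(height·weight/3600)) and BMI are derived
deterministically from the simulated height and weight.

**Hematocrit stage.** The published equation is printed with a
log-transformed response, but exponentiating its linear predictor yields
astronomically large values for any physiologic input, while the linear
reading gives 30–45 %. The package therefore defaults to the linear
reading; `default_coefficient_set(htc_log_scale=True)` restores the literal
one.

## Parameters and defaults

* **Population composition** — the reference population uses the source
  training cohort's marginals: origin 96/2/2 % (European / Sub-Saharan
  African / East Asian), ECOG 35/55/5 % and the nine-category tumor mix
  with 48 % lung and 28 % ovarian. The printed ECOG row sums to 95 %;
  every probability map is renormalized to sum to one at validation time
  with a logged notice, and renormalization is idempotent.
* **Age** — group Weibull parameters default to moment matches of the
  cohort's sex-specific summaries (males 62.3 ± 9.3 y, females
  59.1 ± 11.2 y), applied identically to the sarcoma and non-sarcoma groups
  until group-specific values are supplied. Moment matching solves the
  coefficient of variation for the shape by bracketed Brent root-finding
  (cv is strictly decreasing in the shape) and recovers the scale from the
  mean identity; round trips are accurate to 1e-6 relative across
  cv ∈ (0.05, 0.9). cv > 5 is rejected as out of domain.
* **Residual noise** — per-stage sds on the modeled scale: 0.1 for each
  log-scale stage, 4 cm (height), 0.3 g/dL (albumin), 1.0 g/dL (Hb) and
  3.0 % (hematocrit, a physiologic spread chosen for the one stage the
  documented list does not cover). Draws are kept inside physiologic
  bounds (albumin 1–6 g/dL, Hb 5–20 g/dL, hematocrit 15–60 %, positivity
  elsewhere) by redrawing the residual up to 1000 times and clamping as a
  last resort; with the default sds the bounds sit several sds from the
  means, so truncation bias is negligible (zero-noise refits recover
  coefficients to 1e-13 and noisy refits show no detectable bias at
  n = 200,000).
* **Residual calibration** — when marginal-sd targets are supplied (e.g. a
  published height SD), each targeted stage's sd is solved in network order
  by bisection on the simulated marginal sd under common random numbers,
  to 2 % relative; a target already exceeded by upstream variability alone
  is reported as saturated and assigned sd 0. Targets are expressed on the
  stage's modeled scale (log-sd for log stages).

## Fitting and selection

Refitting is stage-wise ordinary least squares on each stage's modeled
scale, using *observed* upstream covariates (never model predictions), so
stages are independent given the data and permuting a downstream column
cannot change an upstream fit. Rows with missing values in a stage's
variables are dropped per stage (complete-case) with a logged count.
Standard errors are classical homoscedastic OLS; the residual sd estimate is
√(SSE/(n−p)). Rank-deficient designs abort with the near-collinear columns
named. The train/validation splitter draws a seeded permutation with
train size = round(fraction·n); other tools' stratified splitters will not
reproduce identical counts bit-for-bit.

Stepwise selection is bidirectional over candidate term groups (indicator
levels of one covariate move together, as a factor would), minimizing AIC by
default, with BIC and an F-test p-value mode (entry 0.05 / removal 0.10)
available. AIC admits a pure-noise single-df term with probability
P(χ²₁ > 2) ≈ 0.16 — this is inherent to the criterion, not a defect — so
strict type-I control should use BIC, whose inclusion probability at the
cohort sizes involved is below 1 %.

The public surface is a scikit-learn estimator,
`CovariateNetworkModel(coefficients, residuals)`, with `fit` (stage-wise
OLS), `predict` (zero-noise propagation from primaries — the
verification/validation path), `sample` (noisy virtual patients) and
`score` (mean observed-vs-predicted R² across modeled variables);
module-level functions wrap it.

## Validation metrics

Observed-vs-predicted R² is 1 − SSE/SST, computed by default on the modeled
(log where applicable) scale, and classified as excellent (R² > 0.9), good
([0.4, 0.9]), modest ([0.1, 0.4)) or poor; boundary values fall on the
closed side of each printed range, a convention fixed here because the
ranges overlap at their endpoints. Normality screening is a one-sample KS
test with estimated mean/sd (conservative; a Lilliefors correction is
optional) with an automatic log-retry when the raw scale is rejected at
α = 0.05. Cohort-to-cohort distribution comparisons are reduced to
1–99 % quantile grids, normalized histograms and two-sample KS statistics,
exportable as long-format CSV.

## What the generator does and does not emulate

The generator reproduces the *structure* the network encodes: the
population composition, the conditional sex-by-tumor rule, Weibull age, the
coefficient directions (e.g. females 12.81 cm shorter; ECOG 2 adds 0.449 to
log AAG; breast cancer subtracts 2.22 from log CRP) and the induced
correlations among laboratory values. It does not reproduce features of
real cohorts outside the model class: non-Gaussian residuals,
heteroscedasticity, origin×tumor or ECOG×tumor dependence among primaries,
measurement artifacts, or the variables the network does not model
(bilirubin, transaminases, creatinine, INR, glucose…). Passing
parameter-recovery tests on simulated data therefore demonstrates the
correctness and invertibility of the implementation, not the clinical
fidelity of the shipped coefficients to any particular real population —
the residual sds shipped here are documented defaults, not estimates from
patient data.

## Numerical choices

* Multinomial draws use inverse-CDF over the canonical, documented category
  ordering, making output reproducible across platforms; the last
  cumulative bin is pinned to 1 to absorb rounding.
* Age truncation uses vectorized rejection sampling (up to 1000 rounds,
  then clamping); bounds retaining < 1 % of the mass are rejected as a
  configuration error.
* Master-seed → per-scenario streams derive from
  `SeedSequence([seed, crc32(name)])`, so adding or removing a scenario
  never perturbs another scenario's draws.
* Cohort CSVs carry one `#`-prefixed provenance line (seed, config hash,
  row count) and shortest-roundtrip float formatting, so read∘write is the
  identity on values.
* Test and example problem sizes: exactness checks run at n ≈ 3000 (they
  are noise-free), stochastic checks at n = 20,000–100,000, and the
  parameter-recovery exercise at n = 200,000, where every published
  coefficient is recovered within 2 OLS standard errors and the large
  ones within 1 % relative.

## Known limitations

* The four age groups share sex-level parameters by default; genuine
  sarcoma/non-sarcoma age differences require user-supplied overrides.
* ECOG and origin are independent of tumor type by construction, although
  real cohorts show ECOG-by-tumor association.
* The network is valid only inside the adult, ECOG ≤ 2 covariate ranges it
  was built from; pediatric or high-ECOG extrapolation is out of scope.
* The N-L stage's log-AAG coefficient (−0.0073) is two orders of magnitude
  smaller than its albumin coefficient and is implemented as printed.
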