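# Methods

`hystecon` implements a societal-perspective cost-minimization analysis of
three surgical approaches to total hysterectomy for endometrial cancer —
open abdominal (TAH), conventional laparoscopic (TLH) and robot-assisted
laparoscopic (TRH). Effectiveness (successful removal of the uterus with
equivalent short-term outcomes) is assumed equal across methods, so the
comparison reduces to expected societal cost per encounter. This note
documents the model, its parameters, the synthetic-data generator, the
numerical choices and the known limitations.

## 1. The cost model

### Operative charge

Operating-room occupancy is the dominant cost driver. Time is billed on a
graduated fee schedule in 15-minute increments: a case occupying `t` minutes
is charged for `k = ceil(t / 15)` increments, each at its tier's rate (the
default schedule is flat: one repeated rate; a tier list is supported, with
the last tier extending indefinitely). The resulting charge is a
nondecreasing step function of `t`, constant on each half-open interval
`((k−1)·15, k·15]`.

Equipment is charged as `time_charge / ρ` with `ρ = 190` (the observed ratio
of time charges to equipment charges), plus a flat robot-amortization fee
`f` for every robotic case. A per-method flat equipment fee is available as
an alternative policy.

The two unpublished parameters — the per-increment rate `r` and the robot
fee `f` — are identified by least squares from the per-method mean OR times
(192.28, 186.80, 252.6 min, i.e. 13, 13 and 17 increments) and the
per-method mean operative charges ($33,756; $33,706; $44,698):

    C_m = k_m · r · (1 + 1/ρ) + f · [m is robotic]

With two distinct increment counts the system is over-determined by one
equation; the fit gives `r ≈ $2,581.11` per increment and `f ≈ $588.23`,
reproducing each published mean charge within 0.08%. Calibration refuses
degenerate inputs (all methods billing the same number of increments) and,
by default, any fit that misses the published means by more than 2%.

### Nonoperative and indirect costs

Nonoperative encounter charges (hospitalization beyond the operation) are
the difference between each method's mean total encounter charge and its
mean operative charge: $20,354 (TAH), $5,661 (TLH), $6,854 (TRH). The large
abdominal value reflects its longer length of stay.

Indirect societal cost is valued by the human-capital (absenteeism)
approach: published return-to-work intervals — 38–41 days after open
surgery, 19–24 days after either minimally invasive approach (robotic
assumed equal to laparoscopic) — are reduced to a point estimate (midpoint
by default; lower/upper configurable) and priced at median weekly earnings
of $657 spread over a calendar week ($93.86/day). Whether absence days are
calendar or working days is not specified in the source material; calendar
days is the default because return-to-work intervals are conventionally
reported in calendar time, and a 5-day work-week convention is available in
configuration. An `employment_adjustment` factor (default 1.0) stands in
for the unpublished employment-rate correction. All currency is unitless
USD-2009; no inflation adjustment is applied. An optional cost-to-charge
multiplier (restricted to the conventional 0.5–0.7 band) converts the
charge components — never the wage component — from billed charges to
approximate costs.

### Dispersion parameters recovered from interval estimates

The published dispersion "(a, b)" pairs for OR time, blood loss and length
of stay are 95% confidence intervals of the mean, not SDs: their
half-widths scale exactly as `1/√n` across the three cohorts with a common
pooled SD (≈48.8 min for OR time). Cohort SDs are therefore recovered as
`half-width · √n / 1.96`, giving ≈48.8 min (OR time, all methods), ≈175–184
mL (EBL) and ≈1.55–1.64 d (LOS).

## 2. The decision tree

Each method's subtree branches on three independent chance events:
lymph-node dissection (LND, performed for surgical staging), conversion to
open laparotomy (minimally invasive methods only — the abdominal subtree has
no conversion node), and hemorrhage (estimated blood loss ≥ 1000 mL). The
added cost of an event is the cost of the extra OR time it requires, so a
terminal node's OR time is the base time plus the added times of its true
flags, and its cost is the full societal cost at that time. Default added
times are whole billing increments — LND +30 min, conversion +60 min,
hemorrhage +30 min. These are configuration values, not published
quantities (the source states only that LND adds more than one 15-minute
increment); threshold results below are robust to ±1 increment in each.

Branch probabilities are the observed per-method event proportions: LND
74.0% / 38.5% / 37.9%; conversion 0 / 5.1% / — ; hemorrhage 1.45% / 0.91% /
0 (TAH / TLH / TRH). No robotic conversion was observed, so that
probability must be supplied explicitly; the shipped default of 0.03
(sd 0.015 in the probabilistic analysis) is a clearly labelled placeholder
of literature magnitude, not an observed value. Expected cost is evaluated
by rollback (recursive probability-weighted averaging), which is verified
against exhaustive path enumeration; methods are ranked ascending, ties
broken in the fixed order TAH < TLH < TRH and flagged.

With the calibrated schedule and default parameters the expected societal
costs are $43,984 (TLH) < $55,848 (TRH) < $61,708 (TAH). These sit within
2–7% of the published model's figures ($41,339 / $54,062 / $59,997), which
were produced from patient-level ledger data that is not available; the
ordering and the gaps between methods are the reproducible content.

## 3. Sensitivity analyses

**One-way OR-time sweeps.** One method's base OR time is swept over a grid
(by default its cohort interquartile range, computed from the generated
cohort because the source does not print those percentiles) while the other
methods stay at their default expected costs. Curves are step functions
with jumps only at 15-minute boundaries.

**Threshold solving.** The cost-equivalence threshold between a swept
method `a` and a fixed method `b` is the smallest grid time (1-minute
steps over [15, 900]) at which `a`'s expected cost reaches `b`'s default
expected cost; because the curve is a step function this lands on the first
minute of a billing increment, and the billing-increment index is reported
alongside. Absence of a crossing is a result ("none in range"), not an
error. Under default calibration the robotic-vs-abdominal threshold is
286 minutes (billing increment 20, covering 285–300 min), consistent with
the published "approximately 300 minutes". The target for the comparison is
evaluated with the same arithmetic kernel as the sweep so that
exact-equality crossings resolve deterministically.

## 4. Monte Carlo probabilistic sensitivity analysis

Each sampled parameter receives a normal distribution centred on its point
estimate whose spread is its *sampling* uncertainty: the binomial standard
error `√(p(1−p)/n)` for event probabilities. Draws are made by inverse CDF
on uniform streams — exact truncated sampling with no probability atoms at
the bounds — with common random numbers across methods (the same uniform
stream feeds the corresponding parameter slot of every method) so that
incremental comparisons are paired.

Two deliberate design choices keep the simulation an *unbiased* propagation
of parameter uncertainty:

- **Mean-preserving truncation.** Probabilities are truncated to [0, 1].
  For near-zero rates (hemorrhage ≈ 1%, SE ≈ 1.4%) plain truncation would
  shift the sampled mean upward by ~0.4 percentage points. The parent
  normal's location is therefore solved (Brent's method) so the truncated
  mean equals the point estimate — the truncated-normal analogue of the
  moment-matched bounded distributions conventionally used in probabilistic
  sensitivity analysis. Matching falls back to plain truncation when the
  target mean lies on or outside the bounds.
- **Degenerate OR-time spec by default.** The expected-cost operator is
  multilinear in the branch probabilities, so sampling them propagates
  without bias; pushing OR-time draws through the stepped billing schedule
  would instead add a discretization bias of up to one increment (~$800) to
  the mean. By default only the three clinical outcome probabilities are
  sampled; `or_time_se_spec` builds a standard-error OR-time spread for
  callers who explicitly want time uncertainty included (at the price of
  that bias).

Consequently a zero-variance configuration reproduces the deterministic
expected cost exactly, and at any n the PSA mean is an unbiased estimate of
it. Parameters the cohort estimates with zero variance are held constant
unless flagged as literature-sourced, in which case an explicit distribution
is required (the robotic conversion probability); a flagged parameter
without one is a configuration error. The incremental distribution
`Δ = cost_TRH − cost_TAH` is summarized by `P(Δ < 0)`, the probability that
the robotic approach is cheaper per iteration.

## 5. The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes: per
method (n = 73 / 118 / 43 by default), continuous covariates (age, BMI,
uterine weight, OR time, EBL, length of stay) are truncated normals with
the published means and the SDs of §1, truncated at the published cohort
ranges where available and at physical bounds (0) otherwise; binary
covariates and outcomes are independent Bernoulli draws at the published
proportions. One master seed drives per-(method, field) substreams keyed by
a stable hash, so reconfiguring one field never perturbs another — cohorts
are reproducible byte-for-byte.

Hemorrhage can be derived from the sampled EBL (≥ 1000 mL) or forced to a
configured Bernoulli rate. The default is the rate mode: under the normal
EBL assumption the derived exceedance probability is ~10⁻⁵, orders of
magnitude below the observed ~1% rates, because real blood-loss
distributions are heavily right-skewed while the published model substitutes
normals. The EBL-derived mode is retained for consistency checks, and a
lognormal EBL is a straightforward extension.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: covariates are sampled independently (no
correlation between, e.g., BMI and OR time, or adhesions and conversion);
there is no confounding by indication (in practice surgically complex
patients are steered toward the open approach); truncation at 0 makes the
generated EBL means sit above the configured means (the parameter-recovery
suite therefore checks sample moments against the *analytic truncated*
moments, not the raw configured values); and no missingness is generated.

## 6. Numerical choices

- Increment counting uses `ceil(t/15 − 10⁻⁹)`: an OR time landing on an
  increment boundary up to float rounding does not spill into the next
  increment.
- Percentiles use linear interpolation (NumPy default, type 7).
- Sample SDs use the n−1 denominator; 95% CIs are mean ± 1.96·sd/√n; a
  single observation reports its value with SD and CI as missing.
- Group tests: chi-square without continuity correction, switching to the
  exact conditional test (Fisher; Freeman–Halton for 2×3, enumerated in
  integer arithmetic so point-probability comparisons are exact) when any
  expected cell count is below 5; one-way ANOVA with pairwise two-sided
  t-tests Bonferroni-corrected ×3 when the omnibus p < 0.01; α = 0.01
  throughout. A constant variable raises a degenerate-test error.
- Chance-node probabilities must sum to 1 within 10⁻⁹; ranking ties are
  declared at 10⁻¹² relative tolerance.
- Event independence at the chance nodes and per-method (not per-terminal)
  indirect costs follow the published model structure; an optional flag to
  re-assign converted cases to the abdominal recovery interval is a natural
  extension and is deliberately not enabled by default.

## 7. Problem sizes used by the shipped checks

The test suite generates cohorts of 73/118/43 (structure checks), 100,000
(binomial-interval check) and 3×50,000 (parameter recovery); the PSA checks
use 10,000 iterations for the incremental comparison and 100,000 for the
convergence check; rollback is verified against path enumeration on 200
random trees of depth ≤ 6. The full suite runs in a few seconds on one CPU.

## 8. Known limitations

- Charges, not costs: all direct components are hospital charges (an upper
  bound on payments); the cost-to-charge multiplier is exposed but off by
  default, matching the source analysis.
- The fee calibration assumes a flat per-increment rate; if the true
  schedule is graduated, `r` is an average rate and the threshold shifts
  accordingly.
- The robotic conversion probability and the added event times are
  placeholders; conclusions that depend on them (the threshold, the
  incremental PSA) should be read with their sensitivity ranges.
- The retrospective cohort's selection bias is inherited, not modelled: the
  generator reproduces the observed per-method distributions, including
  whatever case-mix differences produced them.
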