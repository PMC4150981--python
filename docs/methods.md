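# Methods

## The model

`markovcea` implements a deterministic Markov cohort state-transition
model that projects the long-term health and cost consequences of a
yearly physical-activity and healthy-eating programme offered to people
with mental disorders living in sheltered housing, from a public-payer
perspective. The cohort occupies one of nine mutually exclusive states:

```
at risk → {diabetes, CHD 1, stroke 1, colon cancer 1, dead}
diabetes → {colon cancer 1, dead}
CHD 1 / stroke 1 / colon 1       (one-cycle tunnel) → {1+, dead}
CHD 1+ / stroke 1+ / colon 1+    → {dead}
dead                              (absorbing)
```

Cycles are one year. The transition matrix is rebuilt every cycle
because incidence, case fatality and background mortality depend on the
cohort's attained age (start age + elapsed cycles), read from published
5-year age-band tables as a step function; ages beyond the top band
(65–69) clamp to it, a least-assumption extrapolation needed because a
20-year horizon outlives the table from any mid-life start age.

Transitions out of `at risk` are general-population incidences times
mental-disorder relative risks (diabetes 1.77, stroke 1.77, colon cancer
2.90, CHD 1.42 below age 50 and 1.01 from 50) and, in the intervention
arm only, times `1 − r_d`, where the risk reduction
`r_d = (per-unit reduction)_d × ΔBMI` combines the disease- and
sex-specific risk reduction per kg/m² of BMI decrease (diabetes
13.0/11.0 %, CHD 4.7/5.7 %, stroke 6.0/8.5 %, colon 5.2/2.0 % for
men/women) with the programme's between-group BMI change
(ΔBMI = 0.20 kg/m², base case). Diabetics carry an extra transition to
colon cancer equal to 1.33 times the at-risk colon-cancer probability
(see *Convention choices* for the alternative reading). Competing risks
within a row are additive with the residual as a self-loop; if a row
ever exceeds unit mass the run aborts rather than silently
renormalising. First-year disease states are strict one-cycle tunnels.

## Valuation

Each reward row contributes utility-weighted person-years (QALYs,
discounted at 1.5 %/year) and state costs (year-2011 euros, discounted
at 3 %/year). State utilities: at risk 0.71, diabetes 0.63, CHD 0.47 /
0.56, stroke 0.50 / 0.50, colon 0.64 / 0.64 (first / subsequent years),
dead 0. Annual state costs: diabetes 3,312 €, CHD 4,386 / 1,183 €,
stroke 13,319 / 4,756 €, colon cancer 9,575 € (first year; see below).
The intervention arm additionally pays the programme:
35.00 €/participant in years 1, 6, 11 and 16 (a pedometer lasts five
years) and 21.30 € in the other years, charged per enrolled cohort
member. The incremental cost-effectiveness ratio is
`ICER = (cost_I − cost_C)/(QALY_I − QALY_C)`, with dominance labels for
the off-diagonal quadrants and an indeterminate label when the QALY
difference is zero.

## Convention choices

The source publication fixes every number above but leaves the usual
spreadsheet conventions unstated. Each is a switch in `ModelOptions`;
the defaults are the unique combination under which the pipeline
reproduces the published base-case and scenario results, and each was
selected on specific numerical evidence:

* **Reward rows** (`cycle_rewards="both"`): utilities and costs are
  credited on every tabulated occupancy row 0..H — H+1 reward rows for
  an H-cycle horizon. The published five-year control-arm QALYs (4.05
  for men) exceed the hard ceiling of any H-row convention
  (0.71 × 5 = 3.55) but match 0.71 × Σ_{t=0..5} 1.015^−t = 4.11, which
  identifies the convention unambiguously. `"end"` (rows 1..H) and
  `"start"` (rows 0..H−1) are available.
* **Discounting** (`discount_first_cycle=True`): row t is discounted by
  (1+r)^−t with row 0 undiscounted; the alternative shifts the exponent
  by one.
* **Programme cost payer** (`charge_intervention_to="cohort"`): the
  yearly cost is charged per enrolled member, undiminished by deaths.
  The published base-case and full-compliance incremental costs imply
  discounted programme streams of ≈360 € (men) and ≈371 € (women), the
  latter exactly the undiminished 20-year schedule (370.9 €). `"alive"`
  and `"at_risk"` weightings are available.
* **Diabetes→colon basis** (`diabetes_colon_basis="colon"`): the 1.33
  excess colon-cancer risk of diabetics multiplies the at-risk→colon
  probability. The literal alternative (1.33 × the at-risk→diabetes
  probability, available as `"diabetes"`) would give diabetics a 2–3 %
  *annual* colon-cancer probability from age 50 — ~40 % cumulative —
  which is epidemiologically implausible and incompatible with the
  published control-arm costs.
* **Colon follow-up cost** (`colon_followup_cost="first_year"`): the
  single published colon-cancer cost is charged in the first-year state
  only, as a diagnosis/treatment-phase cost; the cost table prints
  separate first-/subsequent-year costs for stroke and CHD but only one
  for colon cancer. Charging it lifelong (`"lifelong"`) adds thousands
  of euros per cohort member at mid-life start ages and cannot be
  reconciled with the published control costs.
* **Twice-yearly offer** (`twice_yearly_doubles="all"`): scenario 2
  doubles the full yearly cost; the published scenario-2 incremental
  costs (586/632 €) match full doubling, not a pedometer-sparing rule
  (kept as `"non_pedometer"`).
* **Life-years** are discounted at the QALY rate (1.5 %), switchable to
  undiscounted.

No half-cycle correction is applied anywhere.

## Start-age calibration

The publication never states the cohort's starting age, yet every
outcome depends on it. `calibrate_start_age` grid-searches integer ages
20–65, scoring each candidate by the summed squared relative error of
the **control arm's** discounted QALYs and costs against the published
control base case (men 11.59 QALYs / 8,352 €; women 12.04 / 7,688 €).
Only the comparator enters the score, so the calibration is independent
of every incremental quantity the model is later asked to reproduce.
The bundled tables calibrate to 42 (men) and 43 (women). Fractional
ages are accepted but inert: the age-band step function makes the model
piecewise constant in start age.

With this single free parameter the pipeline reproduces the published
base-case ICERs within ~1 % (men) and ~7 % (women), the scenario ICERs
within ~8 % — except the five-year-horizon ICER for men, which lands
~12 % high: its tiny incremental QALY gain (≈0.0005) is one
band-year of incidence short of the published 0.0006, and the start age
that fixes it (43) degrades the base case. This residual is reported as
is; no scenario-specific recalibration is done.

## Sensitivity analyses

*One-way (tornado):* each key input — the intervention effect (ΔBMI),
the programme cost, each disease cost and each disease's risk
reduction — is scaled to 70 % and 130 % of its base value, the
deterministic pipeline rerun, and parameters ordered by the width of the
resulting ICER range. The 70–130 % range is a screening convention, not
an uncertainty statement.

*Probabilistic (PSA):* every published parameter with a standard error
is sampled per draw — costs from gamma, utilities from beta and total
risk reductions from lognormal distributions, parameterised by method of
moments so the analytic mean and SD equal the published mean and SE
(gamma: shape = (m/s)², scale = s²/m; beta: α+β = m(1−m)/s² − 1;
lognormal: σ² = ln(1+s²/m²), μ = ln m − σ²/2; SE = 0 degenerates to a
point mass). Draws are independent (no correlation structure is
published). Draw order within an iteration is fixed and documented in
`sensitivity.py`, one seeded NumPy generator per run, so same-seed runs
are bit-identical. The control trace is computed once per run (it
depends on no sampled quantity); a draw whose sampled parameters
overflow a transition row is rejected and redrawn, with the count
reported. The published risk-reduction SEs are read on the printed
percent scale (e.g. 2.60 ± 0.003), which makes those draws nearly
degenerate; a `"fraction"` switch reinterprets them 100× larger.

The headline *average ICER* is the ratio of the mean incremental cost to
the mean incremental QALYs: the published PSA means reproduce this
statistic at full precision (221 €/0.00839 ≈ 26,300 €/QALY), whereas the
mean of per-draw ratios is inflated (≈35,000 €/QALY) by near-zero-ΔQALY
draws; both are computed, and per-draw ICERs with |ΔQALY| < 1e−9 are
excluded from the ratio average with the count reported. The
cost-effectiveness plane uses x = incremental QALYs, y = incremental
cost, with the willingness-to-pay line Δcost = 30,000 × ΔQALY and the
cost-effective fraction defined by positive net monetary benefit at that
threshold.

## Validation oracle

`microsim_oracle` re-implements the cohort arithmetic as an
individual-level microsimulation: n individuals are walked through the
*same* per-cycle matrices by inverse-CDF sampling. At n = 50,000 every
cycle/state occupancy agrees with the deterministic trace within three
binomial standard errors, which checks the matrix construction and the
propagation independently of the linear-algebra path.

## Synthetic perturbations

`perturbed_parameters(seed, magnitude)` multiplies every epidemiological
probability, effect, cost and utility by independent uniform factors in
[1−m, 1+m] and clips the results back into their legal ranges (keeping
beta parameterisations feasible), always yielding a valid parameter set.
It exercises code paths, invariants and the validator on inputs other
than the published point — it does not emulate sampling variation in
real registry data (no age-structure realism, no correlation between
quantities), so passing property tests demonstrate robustness of the
arithmetic, not calibration to any other population.

## Problem sizes and tolerances

Deterministic runs propagate a 9-state cohort over 20 annual cycles and
complete in milliseconds; the calibration grid is 46 control runs per
sex. The PSA default is the published 10,000 draws (a few seconds). Row
stochasticity is enforced to 1e−12, trace mass to 1e−10. Reported
euros are rounded to whole units and QALYs to two decimals in the CLI;
all internal arithmetic is double precision.

## Known limitations

* Single cohort start age per run; a mixed-age cohort is not modelled.
* No comorbidity states (e.g. diabetes + CHD) — matching the source
  model, which accounts for macrovascular complications inside the
  diabetes cost instead.
* The trial's effect decay after follow-up is not modelled; the yearly
  repeated programme is assumed to maintain ΔBMI for the whole horizon.
* Utilities are flat per state (no age adjustment).
* No acceptability curve across thresholds; a single 30,000 €/QALY line.
* All costs stay in year-2011 euros; no inflation or currency
  conversion.
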