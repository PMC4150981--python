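# markovcea

A Markov cohort cost-effectiveness model of a yearly health-promotion
programme (physical activity + healthy eating) for people with mental
disorders, from a public-payer perspective.

People with severe mental illness carry roughly 1.4–2.9-fold excess risk
of type-2 diabetes, coronary heart disease, stroke and colon cancer,
much of it mediated by excess weight. This package asks the health
economist's question about a modest, repeatable intervention: if a
10-week pedometer-supported programme shifts BMI by 0.20 kg/m² per year
and is re-offered every year, is it worth its ~35 €/participant annual
cost over 20 years?

The model propagates a cohort through nine states — *at risk*,
*diabetes*, first and subsequent years of *CHD*, *stroke* and *colon
cancer*, and *dead* — in one-year cycles with age- and sex-specific
transition probabilities. Disease incidence in the at-risk state is

    p(incidence) = p_general-population(age, sex) × RR_mental-disorder × (1 − r_d)

where the reduction `r_d = (per-unit reduction)_d × ΔBMI` applies in the
intervention arm only. Traces are valued as discounted QALYs (1.5 %/yr)
and euro costs (3 %/yr), and arms are compared by the incremental
cost-effectiveness ratio

    ICER = (cost_I − cost_C) / (QALY_I − QALY_C)   [€/QALY]

against a 30,000 €/QALY willingness-to-pay threshold. Around the base
case the package provides four scenario analyses (full compliance with
ΔBMI 0.33; twice-yearly delivery; a 0.021-per-BMI-unit utility gain;
a 5-year horizon), a 70–130 % one-way tornado analysis, a 10,000-draw
probabilistic sensitivity analysis (gamma costs, beta utilities,
lognormal risk reductions, fitted by method of moments) and an
individual-level microsimulation used as a validation oracle. All input
tables ship with the package; nothing is downloaded.

See `docs/methods.md` for the model's assumptions, the spreadsheet
conventions it had to pin down, and known limitations.

## Worked example

```python
import markovcea as m

params = m.published_parameters()             # bundled published tables
age = m.calibrate_start_age(params, "men")  # -> 42
res = m.run_comparison(params, "base", sex="men", start_age=age)
print(age, round(res.control.qalys, 2), round(res.icer.delta_cost),
      round(res.icer.icer))
```

prints

```
42 11.89 223 27483
```

i.e. with the cohort start age pinned at 42 by the control-arm
calibration, treatment-as-usual men accrue 11.89 discounted QALYs; the
programme costs an extra 223 € per participant and buys 0.0081 QALYs,
an ICER of ≈27,500 €/QALY — cost-effective at the 30,000 €/QALY
threshold. The same from the command line, plus the other analyses:

```sh
markovcea run --scenario base --sex men     # one comparison
markovcea suite                             # 5 scenarios x 2 sexes
markovcea tornado --sex men                 # one-way sensitivity, CSV-able
markovcea psa --n 10000 --seed 1 --sex men  # probabilistic analysis
markovcea fixtures write --outdir params/   # parameter bundle as CSV+YAML
```

The tornado analysis ranks the intervention effect and the programme
cost as the two most influential inputs; the PSA yields a mean QALY gain
of ≈0.008 at a mean extra cost of ≈221 € for men (average ICER ≈27,000
€/QALY with roughly half the draws cost-effective at the threshold).

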