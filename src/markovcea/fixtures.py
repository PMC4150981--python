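"""Published parameter tables as code, plus perturbed sets for testing.

The study's entire parameterisation is printed: age/sex-specific annual
probabilities on 5-year bands (incidence and case fatality of type-2
diabetes, CHD, stroke and colon cancer, plus overall mortality), the
intervention's per-BMI-unit risk reductions, annual state costs and state
utilities with standard errors and distribution families.  This module
holds those numbers verbatim (percent scale, printed precision), builds a
ready-to-run :class:`~markovcea.parameters.ParameterSet`, writes the
bundle to disk as CSV/YAML, and generates random valid perturbations for
property tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .parameters import (
    EPI_QUANTITIES,
    SEXES,
    AgeBand,
    CostTable,
    EffectSpec,
    EpidemiologyTable,
    ModelOptions,
    ParameterSet,
    RelativeRiskSet,
    UtilityTable,
    validate,
    write_parameters,
)

#: Annual probabilities in percent per age band, in EPI_QUANTITIES order:
#: diabetes incidence/fatality; CHD incidence/fatality year 1/follow-up;
#: stroke incidence/fatality year 1/follow-up; colon cancer incidence/
#: fatality; overall mortality.
EPIDEMIOLOGY_MEN = {
    (20, 24): (0.06, 0.12, 0.01, 5.50, 4.87, 0.02, 13.00, 0.16, 0.01, 6.62, 0.08),
    (25, 29): (0.10, 0.13, 0.02, 5.50, 4.87, 0.03, 13.00, 0.18, 0.01, 6.62, 0.09),
    (30, 34): (0.17, 0.13, 0.05, 5.50, 4.87, 0.05, 13.00, 0.18, 0.01, 6.62, 0.09),
    (35, 39): (0.28, 0.19, 0.10, 5.50, 4.87, 0.07, 13.00, 0.26, 0.03, 6.62, 0.12),
    (40, 44): (0.48, 0.26, 0.19, 5.50, 4.87, 0.11, 13.00, 0.36, 0.04, 6.62, 0.15),
    (45, 49): (0.78, 0.44, 0.35, 5.50, 4.87, 0.16, 13.00, 0.61, 0.09, 6.62, 0.24),
    (50, 55): (1.18, 0.74, 0.41, 5.50, 4.87, 0.25, 36.00, 1.03, 0.16, 7.70, 0.39),
    (56, 59): (1.65, 1.19, 0.63, 15.30, 13.56, 0.37, 36.00, 1.65, 0.26, 7.70, 0.61),
    (60, 64): (2.08, 1.82, 0.89, 15.30, 13.56, 0.55, 24.00, 2.53, 0.37, 7.70, 0.90),
    (65, 69): (2.46, 2.58, 1.17, 15.30, 13.56, 0.83, 24.00, 3.59, 0.60, 9.77, 1.28),
}

EPIDEMIOLOGY_WOMEN = {
    (20, 24): (0.05, 0.04, 0.01, 7.30, 7.74, 0.02, 25.00, 0.06, 0.01, 5.67, 0.03),
    (25, 29): (0.08, 0.06, 0.02, 7.30, 7.74, 0.03, 25.00, 0.08, 0.01, 5.67, 0.04),
    (30, 34): (0.14, 0.06, 0.03, 7.30, 7.74, 0.04, 25.00, 0.09, 0.01, 5.67, 0.04),
    (35, 39): (0.23, 0.11, 0.05, 7.30, 7.74, 0.06, 25.00, 0.15, 0.03, 5.67, 0.07),
    (40, 44): (0.39, 0.16, 0.08, 7.30, 7.74, 0.09, 25.00, 0.23, 0.04, 5.67, 0.10),
    (45, 49): (0.63, 0.27, 0.13, 7.30, 7.74, 0.13, 25.00, 0.38, 0.09, 5.67, 0.16),
    (50, 55): (0.96, 0.44, 0.16, 7.30, 7.74, 0.20, 18.00, 0.63, 0.16, 6.89, 0.27),
    (56, 59): (1.34, 0.64, 0.27, 17.90, 18.97, 0.30, 18.00, 0.90, 0.26, 6.89, 0.37),
    (60, 64): (1.69, 0.98, 0.41, 17.90, 18.97, 0.44, 23.00, 1.39, 0.38, 6.89, 0.54),
    (65, 69): (2.00, 1.36, 0.62, 17.90, 18.97, 0.67, 23.00, 1.93, 0.60, 8.91, 0.74),
}

#: Risk reduction per kg/m^2 of BMI decrease, in percent.
PER_UNIT_RISK_REDUCTION_PCT = {
    ("diabetes", "men"): 13.0,
    ("diabetes", "women"): 11.0,
    ("chd", "men"): 4.7,
    ("chd", "women"): 5.7,
    ("stroke", "men"): 6.0,
    ("stroke", "women"): 8.5,
    ("colon", "men"): 5.2,
    ("colon", "women"): 2.0,
}

#: SE of the total risk reduction, on the same percent scale as printed.
RISK_REDUCTION_SE_PCT = {
    ("diabetes", "men"): 0.003,
    ("diabetes", "women"): 0.002,
    ("chd", "men"): 0.001,
    ("chd", "women"): 0.001,
    ("stroke", "men"): 0.001,
    ("stroke", "women"): 0.002,
    ("colon", "men"): 0.001,
    ("colon", "women"): 0.001,
}

#: Annual disease-state costs in year-2011 euros: state -> (mean, SE).
#: The single published colon-cancer cost applies to both colon states.
STATE_COSTS_EUR = {
    "diabetes": (3312.0, 331.0),
    "chd_1": (4386.0, 439.0),
    "chd_1plus": (1183.0, 118.0),
    "stroke_1": (13319.0, 1332.0),
    "stroke_1plus": (4756.0, 476.0),
    "colon_1": (9575.0, 958.0),
    "colon_1plus": (9575.0, 958.0),
}

#: State utilities: state -> (mean, SE).
UTILITIES = {
    "at_risk": (0.71, 0.04),
    "diabetes": (0.63, 0.06),
    "chd_1": (0.47, 0.05),
    "chd_1plus": (0.56, 0.06),
    "stroke_1": (0.50, 0.05),
    "stroke_1plus": (0.50, 0.05),
    "colon_1": (0.64, 0.06),
    "colon_1plus": (0.64, 0.06),
    "dead": (0.0, 0.0),
}

#: Published base-case outcomes of the comparator (treatment-as-usual)
#: arm.  The study never reports the cohort's starting age, so these two
#: deterministic control-arm quantities are the calibration targets of the
#: start-age grid search (see :func:`markovcea.scenarios.calibrate_start_age`).
CONTROL_REFERENCE = {
    "men": {"qalys": 11.59, "cost": 8352.0},
    "women": {"qalys": 12.04, "cost": 7688.0},
}


def published_parameters() -> ParameterSet:
    """The published base-case parameterisation as a validated
    :class:`ParameterSet` (all probabilities in printed percent)."""
    bands = tuple(AgeBand(l, u) for (l, u) in EPIDEMIOLOGY_MEN)
    values = {
        "men": {
            q: np.array([EPIDEMIOLOGY_MEN[(b.lower, b.upper)][i] for b in bands])
            for i, q in enumerate(EPI_QUANTITIES)
        },
        "women": {
            q: np.array([EPIDEMIOLOGY_WOMEN[(b.lower, b.upper)][i] for b in bands])
            for i, q in enumerate(EPI_QUANTITIES)
        },
    }
    params = ParameterSet(
        epidemiology=EpidemiologyTable(bands, values),
        relative_risks=RelativeRiskSet(),
        effects=EffectSpec(
            dict(PER_UNIT_RISK_REDUCTION_PCT), dict(RISK_REDUCTION_SE_PCT), 0.20
        ),
        costs=CostTable(dict(STATE_COSTS_EUR)),
        utilities=UtilityTable(dict(UTILITIES)),
        horizon=20,
        start_age=None,
        sex="men",
        threshold=30_000.0,
        options=ModelOptions(),
    )
    issues = validate(params)
    if issues:  # pragma: no cover - the bundled tables are consistent
        raise AssertionError(f"bundled parameter tables invalid: {issues}")
    return params


_PROVENANCE = """\
Parameter bundle provenance
===========================
epidemiology.csv  annual probabilities (%) per sex and 5-year age band:
                  disease incidence and case fatality for type-2 diabetes,
                  CHD (first year / follow-up fatality), stroke (first
                  year / follow-up fatality), colon cancer, and overall
                  mortality, as published for the modelled population.
effects.csv       risk reduction (%) per kg/m^2 BMI decrease per disease
                  and sex, the derived total reduction at the base-case
                  BMI change, and its SE (lognormal in the PSA).
costs.csv         annual disease-state costs, year-2011 euros, with SE
                  (gamma in the PSA).  The single colon-cancer cost is
                  applied to both colon states.
utilities.csv     state utilities with SE (beta in the PSA); dead = 0.
config.yaml       run configuration: horizon, discount rates (costs 3%,
                  QALYs 1.5%), BMI change 0.20 kg/m^2, mental-disorder
                  relative risks, intervention cost components
                  (pedometer 13.70, staff 20.57, admin 0.48, manual 0.25;
                  pedometer life 5 years), willingness-to-pay threshold
                  30,000 euros/QALY, and modelling-convention switches.
"""


def write_published_fixture(outdir: str | Path) -> Path:
    """Write the published parameter bundle to ``outdir`` (CSV + YAML,
    values at printed precision) together with a provenance note."""
    outdir = write_parameters(published_parameters(), outdir)
    (Path(outdir) / "PROVENANCE.txt").write_text(_PROVENANCE)
    return outdir


def perturbed_parameters(
    seed: int, magnitude: float, base: ParameterSet | None = None
) -> ParameterSet:
    """Random valid parameter set for property tests.

    Every epidemiological probability, effect, cost and utility of the
    bundled set is multiplied by an independent factor drawn uniformly
    from ``[1 - magnitude, 1 + magnitude]`` and then clipped back into its
    legal range, so the result always passes :func:`validate`.
    """
    if not 0.0 <= magnitude <= 0.5:
        raise ValueError("magnitude must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    params = (base or published_parameters()).copy()

    def factor(size=None):
        return rng.uniform(1.0 - magnitude, 1.0 + magnitude, size=size)

    epi = params.epidemiology
    for sex in SEXES:
        for q in EPI_QUANTITIES:
            col = epi.values[sex][q] * factor(len(epi.bands))
            epi.values[sex][q] = np.clip(col, 0.0, 100.0)

    params.effects.per_unit_pct = {
        k: v * float(factor()) for k, v in params.effects.per_unit_pct.items()
    }
    params.effects.se_pct = {
        k: v * float(factor()) for k, v in params.effects.se_pct.items()
    }
    # keep total reductions below 100% even at bmi_change extremes
    params.effects.bmi_change = min(
        params.effects.bmi_change * float(factor()), 1.0
    )

    params.costs.state_costs = {
        k: (m * float(factor()), s * float(factor()))
        for k, (m, s) in params.costs.state_costs.items()
    }
    params.costs.pedometer *= float(factor())
    params.costs.staff *= float(factor())

    utils = {}
    for state, (u, se) in params.utilities.utilities.items():
        if state == "dead":
            utils[state] = (0.0, 0.0)
        else:
            u_new = float(np.clip(u * factor(), 0.0, 1.0))
            # keep the beta parameterisation feasible: SE^2 < u(1-u)
            se_cap = 0.9 * np.sqrt(max(u_new * (1.0 - u_new), 1e-12))
            utils[state] = (u_new, float(min(se * factor(), se_cap)))
    params.utilities.utilities = utils

    issues = validate(params)
    if issues:  # pragma: no cover - the clipping above repairs all ranges
        raise AssertionError(f"perturbed parameters invalid: {issues}")
    return params
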