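"""Discounted QALYs, life-years and costs, and incremental comparison.

Per cycle ``t`` (1-based), the cohort accrues

* QALYs: sum over states of occupancy x state utility, discounted at the
  QALY rate (1.5% in the base case),
* costs: occupancy x annual state cost discounted at the cost rate (3%),
  plus — in the intervention arm — the programme cost schedule charged to
  the alive fraction (the programme is re-offered every year; a pedometer
  is bought only every five years),
* life-years: the alive fraction, discounted at the QALY rate.

The default discounting convention leaves the first cycle undiscounted,
factor ``(1+r)^-(t-1)``; the alternative ``(1+r)^-t`` is available via
:class:`~markovcea.parameters.ModelOptions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import DEAD, STATE_INDEX, STATES, CohortTrace
from .parameters import ParameterSet


@dataclass
class EconomicOutcome:
    """Aggregate economic result of one arm, with per-cycle breakdown."""

    qalys: float
    costs: float
    life_years: float
    qalys_undiscounted: float
    costs_undiscounted: float
    life_years_undiscounted: float
    arm: str
    sex: str
    start_age: int
    horizon: int
    per_cycle: pd.DataFrame = field(repr=False, default=None)


@dataclass
class ICERResult:
    """Incremental comparison of intervention vs control.

    ``icer`` is ``delta_cost / delta_qaly`` whenever the QALY difference
    is non-zero; ``label`` classifies the quadrant: ``dominant`` (cheaper
    and more effective), ``dominated`` (costlier and less effective),
    ``indeterminate`` (no QALY difference) or ``icer`` otherwise.
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str


def discount_factor(
    rate: float, cycle: int, first_cycle_undiscounted: bool = True
) -> float:
    """Discount factor for a 1-based cycle.

    Default convention: the first year is undiscounted, so the factor is
    ``(1+rate)^-(cycle-1)``; with ``first_cycle_undiscounted=False`` it is
    ``(1+rate)^-cycle``.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if cycle < 1:
        raise ValueError("cycles are 1-based")
    exponent = cycle - 1 if first_cycle_undiscounted else cycle
    return float((1.0 + rate) ** -exponent)


def discount_factors(rate: float, horizon: int, first_cycle_undiscounted: bool = True) -> np.ndarray:
    """Vector of discount factors for cycles 1..horizon."""
    t = np.arange(1, horizon + 1, dtype=float)
    exponent = t - 1 if first_cycle_undiscounted else t
    return (1.0 + rate) ** -exponent


def intervention_cost_schedule(
    params: ParameterSet, horizon: int, scenario=None
) -> np.ndarray:
    """Programme cost per participant for cycles 1..horizon.

    The full cost (including a pedometer) is charged in cycles 1, 6, 11,
    ... (every ``pedometer_life`` years); the pedometer-free cost in all
    other cycles.  A twice-yearly offer (scenario 2) doubles the yearly
    cost; whether the pedometer component is doubled too is governed by
    ``options.twice_yearly_doubles``.
    """
    costs = params.costs
    t = np.arange(1, horizon + 1)
    pedometer_year = (t - 1) % costs.pedometer_life == 0
    schedule = np.where(pedometer_year, costs.pedometer_year_cost, costs.other_year_cost)
    if scenario is not None and getattr(scenario, "twice_yearly", False):
        if params.options.twice_yearly_doubles == "all":
            schedule = 2.0 * schedule
        else:  # one durable pedometer; double only the recurring components
            schedule = schedule + costs.other_year_cost
    return schedule.astype(float)


def _state_utilities(params: ParameterSet, arm: str, scenario) -> np.ndarray:
    u = np.array([params.utilities.utility(s) for s in STATES])
    if (
        scenario is not None
        and getattr(scenario, "utility_gain", False)
        and arm == "intervention"
    ):
        bmi = getattr(scenario, "bmi_change", None)
        if bmi is None:
            bmi = params.effects.bmi_change
        u[STATE_INDEX["at_risk"]] += params.utilities.utility_gain_per_bmi_unit * bmi
    return u


def accumulate(
    trace: CohortTrace, params: ParameterSet, arm: str | None = None, scenario=None
) -> EconomicOutcome:
    """Turn a cohort trace into discounted QALYs, costs and life-years."""
    arm = arm or trace.arm
    horizon = trace.horizon
    rewards = params.options.cycle_rewards
    if rewards == "start":
        occ = trace.occupancy[:-1]  # distribution each cycle begins with
    elif rewards == "both":
        occ = trace.occupancy  # every tabulated row, horizon + 1 of them
    else:
        occ = trace.occupancy[1:]  # distribution after each cycle's transitions
    missing = [s for s in STATES if s not in params.utilities.utilities]
    if missing:
        raise KeyError(f"no utility for states {missing}")

    utilities = _state_utilities(params, arm, scenario)
    state_costs = np.array([params.costs.state_cost(s) for s in STATES])
    if params.options.colon_followup_cost == "first_year":
        state_costs[STATE_INDEX["colon_1plus"]] = 0.0

    first = params.options.discount_first_cycle
    n_rows = occ.shape[0]
    df_q = discount_factors(params.utilities.discount_rate, n_rows, first)
    df_c = discount_factors(params.costs.discount_rate, n_rows, first)
    df_ly = df_q if params.options.discount_life_years else np.ones(n_rows)

    qaly_t = occ @ utilities
    cost_t = occ @ state_costs
    alive_t = 1.0 - occ[:, DEAD]

    if arm == "intervention":
        schedule = intervention_cost_schedule(params, horizon, scenario)
        if rewards == "both":
            # the programme runs in years 1..horizon; the extra trailing
            # reward row carries no programme cost
            schedule = np.append(schedule, 0.0)
        payer_basis = params.options.charge_intervention_to
        if payer_basis == "at_risk":
            payer = occ[:, STATE_INDEX["at_risk"]]
        elif payer_basis == "cohort":
            payer = np.ones_like(alive_t)  # budgeted per enrolled member
        else:
            payer = alive_t
        cost_t = cost_t + schedule * payer

    per_cycle = pd.DataFrame(
        {
            "cycle": np.arange(n_rows) + (0 if rewards == "both" else 1),
            "qalys": qaly_t * df_q,
            "costs": cost_t * df_c,
            "life_years": alive_t * df_ly,
            "qalys_undiscounted": qaly_t,
            "costs_undiscounted": cost_t,
            "life_years_undiscounted": alive_t,
        }
    )
    return EconomicOutcome(
        qalys=float((qaly_t * df_q).sum()),
        costs=float((cost_t * df_c).sum()),
        life_years=float((alive_t * df_ly).sum()),
        qalys_undiscounted=float(qaly_t.sum()),
        costs_undiscounted=float(cost_t.sum()),
        life_years_undiscounted=float(alive_t.sum()),
        arm=arm,
        sex=trace.sex,
        start_age=trace.start_age,
        horizon=horizon,
        per_cycle=per_cycle,
    )


def compute_icer(
    intervention: EconomicOutcome, control: EconomicOutcome
) -> ICERResult:
    """Incremental cost-effectiveness ratio of intervention vs control."""
    for attr in ("sex", "start_age", "horizon"):
        if getattr(intervention, attr) != getattr(control, attr):
            raise ValueError(
                f"mismatched run configurations: {attr} differs "
                f"({getattr(intervention, attr)} vs {getattr(control, attr)})"
            )
    dc = intervention.costs - control.costs
    dq = intervention.qalys - control.qalys
    if dq == 0.0:
        return ICERResult(dc, dq, None, "indeterminate")
    icer = dc / dq
    if dc < 0 and dq > 0:
        label = "dominant"
    elif dc > 0 and dq < 0:
        label = "dominated"
    else:
        label = "icer"
    return ICERResult(dc, dq, icer, label)
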