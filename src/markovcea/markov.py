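"""Nine-state Markov cohort engine.

The cohort occupies one of nine states: ``at_risk``, ``diabetes``, first
and subsequent years of CHD, stroke and colon cancer, and ``dead``.  Each
cycle is one year; the transition matrix is rebuilt every cycle because
incidence, case fatality and background mortality depend on the cohort's
attained age (start age + elapsed cycles, read off 5-year bands with
clamping above the top band).

Transitions out of ``at_risk`` are the published general-population
incidences multiplied by the mental-disorder relative risks (CHD's factor
switches at age 50) and — in the intervention arm — by one minus the
BMI-mediated risk reduction.  Diabetics carry an additional transition to
colon cancer (1.33 times the at-risk-to-diabetes probability).  First-year
disease states are strict one-cycle tunnels: occupants either die at the
first-year case fatality or move on to the corresponding follow-up state.
``dead`` is absorbing.

A per-individual microsimulation (:func:`microsim_oracle`) samples the
same matrices one jump at a time and serves as an independent check that
the deterministic cohort trace is propagated correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import STATES, ParameterSet

N_STATES = len(STATES)
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
AT_RISK, DIABETES, CHD_1, CHD_1P, STROKE_1, STROKE_1P, COLON_1, COLON_1P, DEAD = range(
    N_STATES
)

#: Allowed (from, to) transitions beside self-loops, per the state diagram.
PERMITTED_TRANSITIONS = frozenset(
    {
        (AT_RISK, AT_RISK), (AT_RISK, DIABETES), (AT_RISK, CHD_1),
        (AT_RISK, STROKE_1), (AT_RISK, COLON_1), (AT_RISK, DEAD),
        (DIABETES, DIABETES), (DIABETES, COLON_1), (DIABETES, DEAD),
        (CHD_1, CHD_1P), (CHD_1, DEAD),
        (CHD_1P, CHD_1P), (CHD_1P, DEAD),
        (STROKE_1, STROKE_1P), (STROKE_1, DEAD),
        (STROKE_1P, STROKE_1P), (STROKE_1P, DEAD),
        (COLON_1, COLON_1P), (COLON_1, DEAD),
        (COLON_1P, COLON_1P), (COLON_1P, DEAD),
        (DEAD, DEAD),
    }
)


class TransitionError(ValueError):
    """A transition row accumulated more than unit probability mass."""


@dataclass
class CohortTrace:
    """State-occupancy fractions per cycle for one arm.

    ``occupancy[t, s]`` is the fraction of the cohort in state ``s`` after
    ``t`` cycles; row 0 is the initial distribution (everyone at risk).
    """

    occupancy: np.ndarray  # (horizon + 1, N_STATES)
    arm: str
    sex: str
    start_age: int
    horizon: int

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (cycle, state, occupancy) table for export/plotting."""
        h = self.occupancy.shape[0]
        return pd.DataFrame(
            {
                "cycle": np.repeat(np.arange(h), N_STATES),
                "state": list(STATES) * h,
                "occupancy": self.occupancy.ravel(),
            }
        )


def _scenario_bmi_change(params: ParameterSet, scenario) -> float:
    if scenario is not None and getattr(scenario, "bmi_change", None) is not None:
        return scenario.bmi_change
    return params.effects.bmi_change


def _scenario_horizon(params: ParameterSet, scenario) -> int:
    if scenario is not None and getattr(scenario, "horizon", None) is not None:
        return scenario.horizon
    return params.horizon


def transition_matrices(
    params: ParameterSet,
    ages: np.ndarray,
    sex: str,
    arm: str,
    scenario=None,
) -> np.ndarray:
    """One-cycle transition matrices for an array of attained ages.

    Returns an array of shape ``(len(ages), 9, 9)``.  Raises
    :class:`TransitionError` if competing risks in any row exceed unit
    mass (rows are never renormalised silently).
    """
    if arm not in ("control", "intervention"):
        raise ValueError(f"unknown arm '{arm}'")
    ages = np.asarray(ages, dtype=float)
    q = params.epidemiology.lookup_many(sex, ages)
    rr = params.relative_risks
    bmi = _scenario_bmi_change(params, scenario)

    rr_chd = np.where(ages < rr.chd_age_cutoff, rr.chd_young, rr.chd_old)
    inc = {
        "diabetes": q["diabetes_incidence"] * rr.diabetes,
        "chd": q["chd_incidence"] * rr_chd,
        "stroke": q["stroke_incidence"] * rr.stroke,
        "colon": q["colon_incidence"] * rr.colon,
    }
    if arm == "intervention":
        eff = {
            d: inc[d] * (1.0 - params.effects.total_reduction(d, sex, bmi))
            for d in inc
        }
    else:
        eff = inc

    if params.options.diabetes_colon_basis == "colon":
        diab_to_colon = inc["colon"] * rr.diabetes_to_colon
    else:
        # at-risk-to-diabetes probability (before any intervention effect)
        diab_to_colon = inc["diabetes"] * rr.diabetes_to_colon

    n = len(ages)
    T = np.zeros((n, N_STATES, N_STATES))
    mort = q["overall_mortality"]

    T[:, AT_RISK, DIABETES] = eff["diabetes"]
    T[:, AT_RISK, CHD_1] = eff["chd"]
    T[:, AT_RISK, STROKE_1] = eff["stroke"]
    T[:, AT_RISK, COLON_1] = eff["colon"]
    T[:, AT_RISK, DEAD] = mort

    T[:, DIABETES, COLON_1] = diab_to_colon
    T[:, DIABETES, DEAD] = q["diabetes_fatality"]

    # first-year tunnels: die or move on, never remain
    T[:, CHD_1, DEAD] = q["chd_fatality_year1"]
    T[:, CHD_1, CHD_1P] = 1.0 - q["chd_fatality_year1"]
    T[:, STROKE_1, DEAD] = q["stroke_fatality_year1"]
    T[:, STROKE_1, STROKE_1P] = 1.0 - q["stroke_fatality_year1"]
    T[:, COLON_1, DEAD] = q["colon_fatality"]
    T[:, COLON_1, COLON_1P] = 1.0 - q["colon_fatality"]

    T[:, CHD_1P, DEAD] = q["chd_fatality_followup"]
    T[:, STROKE_1P, DEAD] = q["stroke_fatality_followup"]
    T[:, COLON_1P, DEAD] = q["colon_fatality"]

    T[:, DEAD, DEAD] = 1.0

    # residual mass stays put (tunnels and dead already sum to one)
    for s in (AT_RISK, DIABETES, CHD_1P, STROKE_1P, COLON_1P):
        out = T[:, s, :].sum(axis=1)
        if np.any(out > 1.0 + 1e-12):
            bad = int(np.argmax(out > 1.0 + 1e-12))
            raise TransitionError(
                f"competing risks exceed unit mass in state '{STATES[s]}' "
                f"at age {ages[bad]:.0f} (total {out[bad]:.4f})"
            )
        T[:, s, s] = 1.0 - out
    return T


def build_transition_matrix(
    params: ParameterSet, age: float, sex: str, arm: str, scenario=None
) -> np.ndarray:
    """One-cycle 9x9 transition matrix at a single attained age."""
    return transition_matrices(params, np.array([age]), sex, arm, scenario)[0]


def _resolve_run(params, sex, start_age):
    sex = sex or params.sex
    start_age = params.start_age if start_age is None else start_age
    if start_age is None:
        raise ValueError(
            "start_age is not part of the published tables and must be "
            "supplied (or calibrated; see scenarios.calibrate_start_age)"
        )
    return sex, float(start_age)


def run_cohort(
    params: ParameterSet,
    arm: str,
    scenario=None,
    sex: str | None = None,
    start_age: int | None = None,
) -> CohortTrace:
    """Propagate the full cohort from the at-risk state.

    The matrix applied between rows ``t-1`` and ``t`` uses attained age
    ``start_age + t - 1``, i.e. ages advance one year per cycle.
    """
    sex, start_age = _resolve_run(params, sex, start_age)
    horizon = _scenario_horizon(params, scenario)
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, AT_RISK] = 1.0
    if horizon > 0:
        ages = start_age + np.arange(horizon)
        mats = transition_matrices(params, ages, sex, arm, scenario)
        for t in range(1, horizon + 1):
            occ[t] = occ[t - 1] @ mats[t - 1]
    return CohortTrace(occ, arm, sex, start_age, horizon)


def microsim_oracle(
    params: ParameterSet,
    arm: str,
    scenario=None,
    n_individuals: int = 50_000,
    seed: int = 0,
    sex: str | None = None,
    start_age: int | None = None,
) -> CohortTrace:
    """Empirical occupancy from simulating individuals one jump at a time.

    Uses exactly the matrices of :func:`run_cohort`; with large ``n`` the
    empirical trace converges to the deterministic one at the binomial
    Monte-Carlo rate, which makes this an independent cross-check of the
    cohort propagation.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be at least 1")
    sex, start_age = _resolve_run(params, sex, start_age)
    horizon = _scenario_horizon(params, scenario)
    rng = np.random.default_rng(seed)

    state = np.full(n_individuals, AT_RISK, dtype=np.int64)
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0] = np.bincount(state, minlength=N_STATES) / n_individuals
    if horizon > 0:
        ages = start_age + np.arange(horizon)
        mats = transition_matrices(params, ages, sex, arm, scenario)
        for t in range(1, horizon + 1):
            cum = np.cumsum(mats[t - 1], axis=1)  # (9, 9) row-wise CDFs
            u = rng.random(n_individuals)
            # next state: first column where the row CDF exceeds u
            state = (u[:, None] >= cum[state]).sum(axis=1)
            occ[t] = np.bincount(state, minlength=N_STATES) / n_individuals
    return CohortTrace(occ, arm, sex, start_age, horizon)
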