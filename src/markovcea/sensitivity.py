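"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis reruns the deterministic pipeline with a single
parameter scaled to 70% and 130% of its base value; the tornado orders
parameters by the width of the resulting ICER range.

The probabilistic analysis samples every published parameter carrying a
standard error from its assigned second-order distribution — annual
costs from a gamma, utilities from a beta, risk reductions from a
lognormal — parameterised by matching the distribution's analytic mean
and SD to the published mean and SE (method of moments).  Each of the
(by default 10,000) draws reruns both arms; the result is summarised by
means, 2.5/97.5 percentile credible intervals, the cost-effectiveness
plane cloud and the fraction of draws cost-effective at the
willingness-to-pay threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import accumulate, compute_icer
from .markov import TransitionError, run_cohort
from .parameters import DISEASES, SEXES, DistributionSpec, ParameterSet
from .scenarios import ScenarioConfig, make_scenario, run_comparison

#: Parameters exposed to the one-way analysis.
ONE_WAY_PARAMETERS = (
    "intervention_effect",
    "intervention_cost",
    "cost_diabetes",
    "cost_chd_1",
    "cost_chd_1plus",
    "cost_stroke_1",
    "cost_stroke_1plus",
    "cost_colon",
    "rr_reduction_diabetes",
    "rr_reduction_chd",
    "rr_reduction_stroke",
    "rr_reduction_colon",
)


@dataclass
class OneWayResult:
    """ICER of the deterministic pipeline with one parameter scaled."""

    parameter: str
    factor_low: float
    factor_high: float
    icer_at_low: float
    icer_at_high: float
    base_icer: float

    @property
    def width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def scale_parameter(params: ParameterSet, parameter: str, factor: float) -> ParameterSet:
    """Independent copy of ``params`` with one named input scaled."""
    out = params.copy()
    if parameter == "intervention_effect":
        out.effects.bmi_change *= factor
    elif parameter == "intervention_cost":
        out.costs.pedometer *= factor
        out.costs.staff *= factor
        out.costs.admin *= factor
        out.costs.manual *= factor
    elif parameter == "cost_colon":
        for state in ("colon_1", "colon_1plus"):
            m, s = out.costs.state_costs[state]
            out.costs.state_costs[state] = (m * factor, s)
    elif parameter.startswith("cost_"):
        state = parameter[len("cost_"):]
        if state not in out.costs.state_costs:
            raise ValueError(f"unknown one-way parameter '{parameter}'")
        m, s = out.costs.state_costs[state]
        out.costs.state_costs[state] = (m * factor, s)
    elif parameter.startswith("rr_reduction_"):
        disease = parameter[len("rr_reduction_"):]
        if disease not in DISEASES:
            raise ValueError(f"unknown one-way parameter '{parameter}'")
        for sex in SEXES:
            out.effects.per_unit_pct[(disease, sex)] *= factor
    else:
        raise ValueError(f"unknown one-way parameter '{parameter}'")
    return out


def one_way(
    params: ParameterSet,
    parameter: str,
    scenario: ScenarioConfig | str = "base",
    sex: str = "men",
    start_age: int | None = None,
    factors: tuple[float, float] = (0.70, 1.30),
) -> OneWayResult:
    """Deterministic ICER with ``parameter`` at 70% and at 130% of base."""
    base = run_comparison(params, scenario, sex=sex, start_age=start_age)
    icers = [
        run_comparison(
            scale_parameter(params, parameter, f), scenario, sex=sex,
            start_age=start_age,
        ).icer.icer
        for f in factors
    ]
    return OneWayResult(parameter, factors[0], factors[1], icers[0], icers[1],
                        base.icer.icer)


def tornado(
    params: ParameterSet,
    scenario: ScenarioConfig | str = "base",
    sex: str = "men",
    start_age: int | None = None,
    parameters: tuple[str, ...] = ONE_WAY_PARAMETERS,
    factors: tuple[float, float] = (0.70, 1.30),
) -> list[OneWayResult]:
    """One-way results for every parameter, widest ICER range first."""
    results = [
        one_way(params, p, scenario, sex, start_age, factors) for p in parameters
    ]
    return sorted(results, key=lambda r: r.width, reverse=True)


def tornado_frame(results: list[OneWayResult]) -> pd.DataFrame:
    """Tornado results as a table ready for a bar plot."""
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in results],
            "icer_at_low": [r.icer_at_low for r in results],
            "icer_at_high": [r.icer_at_high for r in results],
            "base_icer": [r.base_icer for r in results],
            "width": [r.width for r in results],
        }
    )


# ---------------------------------------------------------------------------
# distribution fitting


class Sampler:
    """Random sampler with analytic mean/SD fixed by method of moments."""

    family = "point"

    def __init__(self, mean: float, se: float):
        self.mean = mean
        self.se = se

    def sample(self, rng: np.random.Generator) -> float:
        return self.mean


class GammaSampler(Sampler):
    family = "gamma"

    def __init__(self, mean: float, se: float):
        super().__init__(mean, se)
        self.shape = (mean / se) ** 2
        self.scale = se**2 / mean

    def sample(self, rng):
        return rng.gamma(self.shape, self.scale)


class BetaSampler(Sampler):
    family = "beta"

    def __init__(self, mean: float, se: float):
        super().__init__(mean, se)
        nu = mean * (1.0 - mean) / se**2 - 1.0
        if nu <= 0:
            raise ValueError(
                f"beta distribution infeasible: SE^2 = {se**2:.4g} >= "
                f"mean(1-mean) = {mean * (1 - mean):.4g}"
            )
        self.alpha = mean * nu
        self.beta = (1.0 - mean) * nu

    def sample(self, rng):
        return rng.beta(self.alpha, self.beta)


class LognormalSampler(Sampler):
    family = "lognormal"

    def __init__(self, mean: float, se: float):
        super().__init__(mean, se)
        self.sigma2 = math.log(1.0 + se**2 / mean**2)
        self.mu = math.log(mean) - self.sigma2 / 2.0

    def sample(self, rng):
        return rng.lognormal(self.mu, math.sqrt(self.sigma2))


def fit_distribution(spec: DistributionSpec) -> Sampler:
    """Method-of-moments sampler whose analytic mean and SD equal the
    spec's (mean, SE); an SE of zero yields a point mass."""
    if spec.se < 0:
        raise ValueError("SE must be non-negative")
    if spec.se == 0.0:
        return Sampler(spec.mean, 0.0)
    if spec.family == "gamma":
        if spec.mean <= 0:
            raise ValueError("gamma requires a positive mean")
        return GammaSampler(spec.mean, spec.se)
    if spec.family == "beta":
        if not 0.0 < spec.mean < 1.0:
            raise ValueError("beta requires a mean strictly inside (0, 1)")
        return BetaSampler(spec.mean, spec.se)
    if spec.family == "lognormal":
        if spec.mean <= 0:
            raise ValueError("lognormal requires a positive mean")
        return LognormalSampler(spec.mean, spec.se)
    raise ValueError(f"unknown distribution family '{spec.family}'")


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

#: Fixed draw order of one PSA iteration (determinism contract): the six
#: published state costs (the colon cost is drawn once and applied to both
#: colon states), the two programme-cost levels, the eight non-dead state
#: utilities, then the eight disease-by-sex risk reductions.
PSA_COST_ITEMS = ("diabetes", "chd_1", "chd_1plus", "stroke_1", "stroke_1plus", "colon")
PSA_UTILITY_ITEMS = (
    "at_risk", "diabetes", "chd_1", "chd_1plus",
    "stroke_1", "stroke_1plus", "colon_1", "colon_1plus",
)
PSA_REDUCTION_ITEMS = tuple((d, s) for d in DISEASES for s in SEXES)


@dataclass
class PSAResult:
    """Per-draw incremental outcomes and their summaries."""

    n: int
    delta_qaly: np.ndarray = field(repr=False)
    delta_cost: np.ndarray = field(repr=False)
    icer: np.ndarray = field(repr=False)  # NaN where |delta QALY| ~ 0
    threshold: float
    n_rejected: int
    n_icer_excluded: int
    seed: int

    @property
    def mean_delta_qaly(self) -> float:
        return float(self.delta_qaly.mean())

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    @property
    def mean_icer(self) -> float:
        """Headline average ICER: mean of the per-draw ratios."""
        return float(np.nanmean(self.icer))

    @property
    def icer_of_means(self) -> float:
        """Alternative average: ratio of mean increments."""
        return self.mean_delta_cost / self.mean_delta_qaly

    def credible_interval(self, which: str, level: float = 0.95) -> tuple[float, float]:
        values = {"delta_qaly": self.delta_qaly, "delta_cost": self.delta_cost,
                  "icer": self.icer[~np.isnan(self.icer)]}[which]
        lo, hi = np.percentile(values, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
        return float(lo), float(hi)

    @property
    def fraction_below_threshold(self) -> float:
        """Fraction of draws with positive net monetary benefit at the
        willingness-to-pay threshold (the cloud's cost-effective side)."""
        nmb = self.threshold * self.delta_qaly - self.delta_cost
        return float((nmb > 0).mean())

    def ce_plane(self) -> pd.DataFrame:
        """Cost-effectiveness plane cloud: x = incremental effectiveness
        (QALYs), y = incremental cost (euros)."""
        return pd.DataFrame(
            {"delta_qaly": self.delta_qaly, "delta_cost": self.delta_cost}
        )

    def summary(self) -> dict:
        ci_q = self.credible_interval("delta_qaly")
        ci_c = self.credible_interval("delta_cost")
        ci_i = self.credible_interval("icer")
        return {
            "n": self.n,
            "seed": self.seed,
            "mean_delta_qaly": self.mean_delta_qaly,
            "ci_delta_qaly": ci_q,
            "mean_delta_cost": self.mean_delta_cost,
            "ci_delta_cost": ci_c,
            "mean_icer": self.mean_icer,
            "ci_icer": ci_i,
            "icer_of_means": self.icer_of_means,
            "threshold": self.threshold,
            "fraction_below_threshold": self.fraction_below_threshold,
            "n_rejected": self.n_rejected,
            "n_icer_excluded": self.n_icer_excluded,
        }


def _draw_samplers(params: ParameterSet, bmi_change: float):
    specs = params.distribution_specs()
    samplers = {
        "costs": [fit_distribution(specs[f"cost:{item if item != 'colon' else 'colon_1'}"])
                  for item in PSA_COST_ITEMS],
        "intervention": [
            fit_distribution(specs["cost:intervention_pedometer_year"]),
            fit_distribution(specs["cost:intervention_other_year"]),
        ],
        "utilities": [fit_distribution(specs[f"utility:{s}"]) for s in PSA_UTILITY_ITEMS],
        # lognormal on the total reduction at the scenario's BMI change
        "reductions": [],
    }
    for d, s in PSA_REDUCTION_ITEMS:
        se = params.effects.se_pct[(d, s)]
        if params.options.rr_reduction_se_scale == "fraction":
            se *= 100.0
        mean = params.effects.per_unit_pct[(d, s)] * bmi_change
        samplers["reductions"].append(
            fit_distribution(DistributionSpec("lognormal", mean, se))
        )
    return samplers


def _apply_draw(params: ParameterSet, samplers, rng, bmi_change: float) -> ParameterSet:
    draw = params.copy()
    for item, sampler in zip(PSA_COST_ITEMS, samplers["costs"]):
        value = sampler.sample(rng)
        targets = ("colon_1", "colon_1plus") if item == "colon" else (item,)
        for state in targets:
            _, se = draw.costs.state_costs[state]
            draw.costs.state_costs[state] = (value, se)
    draw.costs.pedometer_year_override = samplers["intervention"][0].sample(rng)
    draw.costs.other_year_override = samplers["intervention"][1].sample(rng)
    for state, sampler in zip(PSA_UTILITY_ITEMS, samplers["utilities"]):
        _, se = draw.utilities.utilities[state]
        draw.utilities.utilities[state] = (min(sampler.sample(rng), 1.0), se)
    for (d, s), sampler in zip(PSA_REDUCTION_ITEMS, samplers["reductions"]):
        # store as per-unit value so total_reduction() reproduces the draw
        draw.effects.per_unit_pct[(d, s)] = sampler.sample(rng) / bmi_change
    return draw


def run_psa(
    params: ParameterSet,
    scenario: ScenarioConfig | str = "base",
    sex: str = "men",
    n: int = 10_000,
    seed: int = 0,
    start_age: int | None = None,
    icer_tol: float = 1e-9,
) -> PSAResult:
    """Monte-Carlo propagation of all second-order parameter uncertainty.

    Per draw, every published (mean, SE) parameter is sampled in a fixed,
    documented order from one seeded generator, both arms are rerun, and
    the incremental outcomes recorded.  Draws whose sampled parameters
    make a transition row exceed unit mass are rejected and redrawn (the
    count is reported).  Per-draw ICERs with ``|delta QALY| < icer_tol``
    are excluded from the average-ratio statistic (count reported).
    """
    if n < 2:
        raise ValueError("a probabilistic analysis needs at least 2 draws")
    if isinstance(scenario, str):
        scenario = make_scenario(scenario)
    sex = sex or params.sex
    start_age = params.start_age if start_age is None else start_age
    bmi = scenario.bmi_change if scenario.bmi_change is not None else params.effects.bmi_change

    rng = np.random.default_rng(seed)
    samplers = _draw_samplers(params, bmi)

    # the control trace ignores costs, utilities and reductions, so it is
    # identical across draws and computed once
    control_trace = run_cohort(params, "control", scenario, sex=sex, start_age=start_age)

    dq = np.empty(n)
    dc = np.empty(n)
    icers = np.full(n, np.nan)
    n_rejected = 0
    for i in range(n):
        for _attempt in range(100):
            draw = _apply_draw(params, samplers, rng, bmi)
            try:
                trace_i = run_cohort(draw, "intervention", scenario, sex=sex,
                                     start_age=start_age)
            except TransitionError:
                n_rejected += 1
                continue
            break
        else:  # pragma: no cover - would need pathological SEs
            raise TransitionError("100 consecutive infeasible PSA draws")
        out_c = accumulate(control_trace, draw, "control", scenario)
        out_i = accumulate(trace_i, draw, "intervention", scenario)
        dq[i] = out_i.qalys - out_c.qalys
        dc[i] = out_i.costs - out_c.costs
        if abs(dq[i]) >= icer_tol:
            icers[i] = dc[i] / dq[i]
    n_excluded = int(np.isnan(icers).sum())
    return PSAResult(
        n=n,
        delta_qaly=dq,
        delta_cost=dc,
        icer=icers,
        threshold=params.threshold,
        n_rejected=n_rejected,
        n_icer_excluded=n_excluded,
        seed=seed,
    )
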