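"""Typed model parameters, file I/O and validation.

Every number the cohort model consumes lives in a :class:`ParameterSet`:
age/sex-specific incidence and case-fatality probabilities, the
mental-disorder relative risks, the per-BMI-unit risk reductions of the
intervention, annual state costs, state utilities, discount rates and the
probabilistic-sensitivity distribution assignments.

Probabilities are stored exactly as published — annual percentages on
5-year age bands — and converted to per-cycle fractions at lookup time, so
that a parameter file written by :func:`write_parameters` round-trips to
the printed precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SEXES = ("men", "women")
DISEASES = ("diabetes", "chd", "stroke", "colon")

#: Ordered health states of the cohort model.  The four chronic diseases
#: are split into a first-year ("tunnel") state and a subsequent-years
#: state except diabetes, which has a single state.
STATES = (
    "at_risk",
    "diabetes",
    "chd_1",
    "chd_1plus",
    "stroke_1",
    "stroke_1plus",
    "colon_1",
    "colon_1plus",
    "dead",
)

#: Column order of the epidemiology table: one annual percentage per
#: (sex, age band) for each quantity.
EPI_QUANTITIES = (
    "diabetes_incidence",
    "diabetes_fatality",
    "chd_incidence",
    "chd_fatality_year1",
    "chd_fatality_followup",
    "stroke_incidence",
    "stroke_fatality_year1",
    "stroke_fatality_followup",
    "colon_incidence",
    "colon_fatality",
    "overall_mortality",
)

DISTRIBUTION_FAMILIES = ("gamma", "beta", "lognormal")


class ParameterError(ValueError):
    """Raised when a parameter file cannot be interpreted."""


@dataclass(frozen=True)
class AgeBand:
    """Closed age interval [lower, upper] in whole years."""

    lower: int
    upper: int

    def __contains__(self, age: float) -> bool:
        return self.lower <= age <= self.upper

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.lower}-{self.upper}"


@dataclass
class EpidemiologyTable:
    """Annual disease incidence, case fatality and overall mortality.

    Values are stored as percentages on the published 5-year age bands;
    :meth:`lookup` reads the table as a step function of age and returns a
    per-cycle fraction.
    """

    bands: tuple[AgeBand, ...]
    #: sex -> quantity -> array of percentages aligned with ``bands``
    values: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        self._lowers = np.array([b.lower for b in self.bands])

    def band_index(self, age: float) -> int:
        """Index of the band containing ``age``; ages above the top band
        clamp to the last band (the model horizon outlives the table)."""
        if age < self.bands[0].lower:
            raise ValueError(
                f"age {age} is below the youngest tabulated band "
                f"({self.bands[0]})"
            )
        idx = int(np.searchsorted(self._lowers, age, side="right")) - 1
        return min(idx, len(self.bands) - 1)

    def lookup(self, sex: str, age: float, quantity: str) -> float:
        """Annual probability (fraction) of ``quantity`` at attained age."""
        return float(self.values[sex][quantity][self.band_index(age)]) / 100.0

    def lookup_many(self, sex: str, ages: np.ndarray) -> dict[str, np.ndarray]:
        """Vector of fractions per quantity for an array of attained ages."""
        idx = np.minimum(
            np.searchsorted(self._lowers, ages, side="right") - 1,
            len(self.bands) - 1,
        )
        if np.any(ages < self.bands[0].lower):
            raise ValueError("age below the youngest tabulated band")
        return {q: self.values[sex][q][idx] / 100.0 for q in EPI_QUANTITIES}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            for i, band in enumerate(self.bands):
                row = {"sex": sex, "age_lower": band.lower, "age_upper": band.upper}
                row.update({q: self.values[sex][q][i] for q in EPI_QUANTITIES})
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EpidemiologyTable":
        missing = {"sex", "age_lower", "age_upper", *EPI_QUANTITIES} - set(frame.columns)
        if missing:
            raise ParameterError(f"epidemiology table missing columns: {sorted(missing)}")
        bands = sorted(
            {(int(l), int(u)) for l, u in zip(frame["age_lower"], frame["age_upper"])}
        )
        values: dict[str, dict[str, np.ndarray]] = {}
        for sex in SEXES:
            sub = frame[frame["sex"] == sex].sort_values("age_lower")
            values[sex] = {q: sub[q].to_numpy(dtype=float) for q in EPI_QUANTITIES}
        return cls(tuple(AgeBand(l, u) for l, u in bands), values)


@dataclass
class RelativeRiskSet:
    """Disease-risk multipliers for the mental-disorder population
    relative to the general population, plus the diabetes-to-colon-cancer
    multiplier.  CHD risk is age dependent (elevated below 50)."""

    diabetes: float = 1.77
    stroke: float = 1.77
    chd_young: float = 1.42
    chd_old: float = 1.01
    colon: float = 2.90
    diabetes_to_colon: float = 1.33
    chd_age_cutoff: int = 50

    def chd(self, age: float) -> float:
        return self.chd_young if age < self.chd_age_cutoff else self.chd_old

    def for_disease(self, disease: str, age: float) -> float:
        if disease == "chd":
            return self.chd(age)
        return getattr(self, disease)


@dataclass
class EffectSpec:
    """Intervention effect: BMI change and per-BMI-unit risk reductions.

    ``per_unit_pct[(disease, sex)]`` is the percentage risk reduction per
    kg/m^2 of BMI decrease; the total reduction applied in the model is
    ``per_unit_pct * bmi_change``.  ``se_pct`` is the standard error of the
    total reduction on the same (percent) scale as published.
    """

    per_unit_pct: dict[tuple[str, str], float]
    se_pct: dict[tuple[str, str], float]
    bmi_change: float = 0.20

    def total_reduction(
        self, disease: str, sex: str, bmi_change: float | None = None
    ) -> float:
        """Total relative risk reduction as a fraction in [0, 1)."""
        bmi = self.bmi_change if bmi_change is None else bmi_change
        return self.per_unit_pct[(disease, sex)] * bmi / 100.0

    def total_reduction_pct(self, disease: str, sex: str) -> float:
        return self.per_unit_pct[(disease, sex)] * self.bmi_change


@dataclass
class CostTable:
    """Annual state costs (year-2011 euros) and the programme cost.

    The programme cost per participant is the sum of four components; a
    pedometer lasts ``pedometer_life`` years, so the full cost recurs only
    every fifth cycle and the pedometer-free cost is charged in between.
    """

    state_costs: dict[str, tuple[float, float]]  # state -> (mean, SE)
    pedometer: float = 13.70
    staff: float = 20.57
    admin: float = 0.48
    manual: float = 0.25
    pedometer_life: int = 5
    pedometer_year_se: float = 3.50
    other_year_se: float = 2.13
    discount_rate: float = 0.03
    # set by probabilistic draws to replace the component sums
    pedometer_year_override: float | None = None
    other_year_override: float | None = None

    @property
    def pedometer_year_cost(self) -> float:
        """Programme cost in a year a pedometer is handed out."""
        if self.pedometer_year_override is not None:
            return self.pedometer_year_override
        # euro amounts; round away binary float dust from the summation
        return round(self.pedometer + self.staff + self.admin + self.manual, 10)

    @property
    def other_year_cost(self) -> float:
        """Programme cost in the years in between."""
        if self.other_year_override is not None:
            return self.other_year_override
        return round(self.staff + self.admin + self.manual, 10)

    def state_cost(self, state: str) -> float:
        return self.state_costs.get(state, (0.0, 0.0))[0]


@dataclass
class UtilityTable:
    """Health-state utilities (EQ-5D-type weights in [0, 1], dead = 0)."""

    utilities: dict[str, tuple[float, float]]  # state -> (mean, SE)
    discount_rate: float = 0.015
    utility_gain_per_bmi_unit: float = 0.021

    def utility(self, state: str) -> float:
        return self.utilities[state][0]


@dataclass(frozen=True)
class DistributionSpec:
    """Second-order uncertainty of one parameter: family, mean and SE."""

    family: str
    mean: float
    se: float


@dataclass
class ModelOptions:
    """Switchable modelling conventions.

    The source publication leaves several spreadsheet conventions
    unstated; each is exposed as a switch, and the defaults are the
    combination that reproduces the published deterministic results (see
    the methods note for the selection evidence).

    discount_first_cycle
        ``True`` (default): cycle 1 undiscounted, factor ``(1+r)^-(t-1)``;
        ``False``: factor ``(1+r)^-t``.
    cycle_rewards
        Occupancy rows that earn utilities and costs: ``"both"``
        (default) credits every tabulated row 0..horizon (the spreadsheet
        convention that counts both end points, horizon+1 reward rows);
        ``"end"`` uses the distribution after each cycle's transitions
        (rows 1..horizon); ``"start"`` the distribution each cycle begins
        with (rows 0..horizon-1).
    charge_intervention_to
        Which fraction of the intervention cohort pays the yearly
        programme cost: ``"cohort"`` (default — the programme is budgeted
        per enrolled member, undiminished by deaths), ``"alive"`` or
        ``"at_risk"``.
    diabetes_colon_basis
        Basis of the diabetes-to-colon-cancer transition: ``"colon"``
        (default — the at-risk-to-colon-cancer probability times 1.33,
        the excess colon-cancer risk of diabetics) or ``"diabetes"`` (the
        at-risk-to-diabetes probability times 1.33, a literal reading of
        the source's wording that makes nearly half of all diabetics
        develop colon cancer over the horizon).
    colon_followup_cost
        ``"first_year"`` (default): the single published colon-cancer
        cost is charged in the first-year state only, like a
        diagnosis/treatment-phase cost; ``"lifelong"`` charges it in the
        follow-up state as well.
    rr_reduction_se_scale
        ``"printed"`` (default): the published SEs of the risk reductions
        are absolute values on the same percent scale as the means;
        ``"fraction"``: reinterpret them as fractions of a unit (i.e. a
        hundred-fold larger relative uncertainty).
    twice_yearly_doubles
        Which programme-cost components a twice-yearly offer doubles:
        ``"all"`` (default) or ``"non_pedometer"`` (a pedometer is durable
        and handed out once regardless).
    discount_life_years
        Discount life-years at the utility rate (default ``True``).
    """

    discount_first_cycle: bool = True
    cycle_rewards: str = "both"
    charge_intervention_to: str = "cohort"
    diabetes_colon_basis: str = "colon"
    colon_followup_cost: str = "first_year"
    rr_reduction_se_scale: str = "printed"
    twice_yearly_doubles: str = "all"
    discount_life_years: bool = True


@dataclass
class ParameterSet:
    """Complete parameterisation of one model run."""

    epidemiology: EpidemiologyTable
    relative_risks: RelativeRiskSet
    effects: EffectSpec
    costs: CostTable
    utilities: UtilityTable
    horizon: int = 20
    start_age: int | None = None
    sex: str = "men"
    threshold: float = 30_000.0
    options: ModelOptions = field(default_factory=ModelOptions)

    def distribution_specs(self) -> dict[str, DistributionSpec]:
        """Every sampled parameter of the probabilistic analysis, keyed by
        a stable name, with its published family, mean and SE."""
        specs: dict[str, DistributionSpec] = {}
        for state, (mean, se) in self.costs.state_costs.items():
            specs[f"cost:{state}"] = DistributionSpec("gamma", mean, se)
        specs["cost:intervention_pedometer_year"] = DistributionSpec(
            "gamma", self.costs.pedometer_year_cost, self.costs.pedometer_year_se
        )
        specs["cost:intervention_other_year"] = DistributionSpec(
            "gamma", self.costs.other_year_cost, self.costs.other_year_se
        )
        for state, (mean, se) in self.utilities.utilities.items():
            if state == "dead":
                continue
            specs[f"utility:{state}"] = DistributionSpec("beta", mean, se)
        for (disease, sex), per_unit in self.effects.per_unit_pct.items():
            se = self.effects.se_pct[(disease, sex)]
            if self.options.rr_reduction_se_scale == "fraction":
                se = se * 100.0
            specs[f"rr_reduction:{disease}:{sex}"] = DistributionSpec(
                "lognormal", per_unit * self.effects.bmi_change, se
            )
        return specs

    def copy(self) -> "ParameterSet":
        """Independent deep copy (for one-way scaling and PSA draws)."""
        return dataclasses.replace(
            self,
            epidemiology=EpidemiologyTable(
                self.epidemiology.bands,
                {
                    sex: {q: v.copy() for q, v in qs.items()}
                    for sex, qs in self.epidemiology.values.items()
                },
            ),
            relative_risks=dataclasses.replace(self.relative_risks),
            effects=EffectSpec(
                dict(self.effects.per_unit_pct),
                dict(self.effects.se_pct),
                self.effects.bmi_change,
            ),
            costs=dataclasses.replace(
                self.costs, state_costs=dict(self.costs.state_costs)
            ),
            utilities=dataclasses.replace(
                self.utilities, utilities=dict(self.utilities.utilities)
            ),
            options=dataclasses.replace(self.options),
        )


# ---------------------------------------------------------------------------
# validation


def validate(params: ParameterSet) -> list[str]:
    """Check every structural invariant; returns the list of violations
    (empty means valid).  Violations are reported as data, not raised."""
    issues: list[str] = []
    epi = params.epidemiology

    lowers = [b.lower for b in epi.bands]
    uppers = [b.upper for b in epi.bands]
    for band in epi.bands:
        if band.lower > band.upper:
            issues.append(f"epidemiology: inverted age band {band}")
    if lowers != sorted(lowers):
        issues.append("epidemiology: age bands are not ordered")
    for (_, u_prev), (l_next, _) in zip(
        zip(lowers, uppers), zip(lowers[1:], uppers[1:])
    ):
        if l_next <= u_prev:
            issues.append(
                f"epidemiology: overlapping age bands at lower bound {l_next}"
            )

    for sex in SEXES:
        if sex not in epi.values:
            issues.append(f"epidemiology: no rows for sex '{sex}'")
            continue
        for q in EPI_QUANTITIES:
            col = epi.values[sex].get(q)
            if col is None:
                issues.append(f"epidemiology: missing column '{q}' for {sex}")
                continue
            if len(col) != len(epi.bands):
                issues.append(
                    f"epidemiology: {sex}/{q} has {len(col)} values for "
                    f"{len(epi.bands)} bands"
                )
                continue
            if np.any(~np.isfinite(col)) or np.any(col < 0) or np.any(col > 100):
                issues.append(
                    f"epidemiology: {sex}/{q} contains a probability outside [0, 100]%"
                )

    for name in ("diabetes", "stroke", "chd_young", "chd_old", "colon", "diabetes_to_colon"):
        if getattr(params.relative_risks, name) <= 0:
            issues.append(f"relative risk '{name}' must be strictly positive")

    for key, per_unit in params.effects.per_unit_pct.items():
        if per_unit < 0:
            issues.append(f"effect: per-unit risk reduction {key} is negative")
    for key, se in params.effects.se_pct.items():
        if se < 0:
            issues.append(f"effect: SE for {key} is negative")
    missing_eff = {(d, s) for d in DISEASES for s in SEXES} - set(
        params.effects.per_unit_pct
    )
    if missing_eff:
        issues.append(f"effect: missing risk reductions for {sorted(missing_eff)}")
    if params.effects.bmi_change < 0:
        issues.append("effect: bmi_change is negative")

    for state, (mean, se) in params.costs.state_costs.items():
        if state not in STATES:
            issues.append(f"cost: unknown state '{state}'")
        if state in ("at_risk", "dead") and mean != 0:
            issues.append(f"cost: state '{state}' must carry zero disease cost")
        if mean < 0:
            issues.append(f"cost: state '{state}' has a negative cost")
        if se < 0:
            issues.append(f"cost: state '{state}' has a negative SE")
    for comp in ("pedometer", "staff", "admin", "manual"):
        if getattr(params.costs, comp) < 0:
            issues.append(f"cost: intervention component '{comp}' is negative")
    if params.costs.pedometer_life < 1:
        issues.append("cost: pedometer life must be at least one year")
    if params.costs.discount_rate < 0:
        issues.append("cost: negative discount rate")

    for state in STATES:
        if state not in params.utilities.utilities:
            issues.append(f"utility: missing state '{state}'")
            continue
        u, se = params.utilities.utilities[state]
        if not (0.0 <= u <= 1.0):
            issues.append(f"utility: state '{state}' utility {u} outside [0, 1]")
        if se < 0:
            issues.append(f"utility: state '{state}' has a negative SE")
    dead = params.utilities.utilities.get("dead")
    if dead is not None and dead[0] != 0.0:
        issues.append("utility: dead state must have utility exactly 0")
    if params.utilities.discount_rate < 0:
        issues.append("utility: negative discount rate")

    if params.horizon < 0:
        issues.append("horizon must be non-negative")
    if params.sex not in SEXES:
        issues.append(f"unknown sex '{params.sex}'")
    if params.start_age is not None and params.start_age < epi.bands[0].lower:
        issues.append("start_age below the youngest tabulated band")
    if params.threshold <= 0:
        issues.append("willingness-to-pay threshold must be positive")

    for name, spec in params.distribution_specs().items():
        if spec.family not in DISTRIBUTION_FAMILIES:
            issues.append(f"distribution '{name}': unknown family '{spec.family}'")

    opt = params.options
    for field_name, allowed in (
        ("cycle_rewards", ("both", "end", "start")),
        ("charge_intervention_to", ("cohort", "alive", "at_risk")),
        ("diabetes_colon_basis", ("colon", "diabetes")),
        ("colon_followup_cost", ("first_year", "lifelong")),
        ("rr_reduction_se_scale", ("printed", "fraction")),
        ("twice_yearly_doubles", ("all", "non_pedometer")),
    ):
        if getattr(opt, field_name) not in allowed:
            issues.append(
                f"options: {field_name} must be one of {allowed}, "
                f"got '{getattr(opt, field_name)}'"
            )

    return issues


def lookup(table: EpidemiologyTable, sex: str, age: float, quantity: str) -> float:
    """Annual probability (fraction) from the epidemiology step function."""
    return table.lookup(sex, age, quantity)


# ---------------------------------------------------------------------------
# file I/O

_EPI_FILE = "epidemiology.csv"
_EFFECTS_FILE = "effects.csv"
_COSTS_FILE = "costs.csv"
_UTILITIES_FILE = "utilities.csv"
_CONFIG_FILE = "config.yaml"


def write_parameters(params: ParameterSet, outdir: str | Path) -> Path:
    """Write a parameter bundle (four CSV tables + a YAML run
    configuration) to ``outdir``; returns the directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params.epidemiology.to_frame().to_csv(outdir / _EPI_FILE, index=False)

    eff_rows = [
        {
            "disease": d,
            "sex": s,
            "per_unit_reduction_pct": params.effects.per_unit_pct[(d, s)],
            "total_reduction_pct": round(
                params.effects.per_unit_pct[(d, s)] * params.effects.bmi_change, 10
            ),
            "se_pct": params.effects.se_pct[(d, s)],
            "distribution": "lognormal",
        }
        for d in DISEASES
        for s in SEXES
    ]
    pd.DataFrame(eff_rows).to_csv(outdir / _EFFECTS_FILE, index=False)

    cost_rows = [
        {"state": state, "annual_cost_eur": mean, "se_eur": se, "distribution": "gamma"}
        for state, (mean, se) in params.costs.state_costs.items()
    ]
    pd.DataFrame(cost_rows).to_csv(outdir / _COSTS_FILE, index=False)

    util_rows = [
        {"state": state, "utility": mean, "se": se,
         "distribution": "beta" if state != "dead" else "point"}
        for state, (mean, se) in params.utilities.utilities.items()
    ]
    pd.DataFrame(util_rows).to_csv(outdir / _UTILITIES_FILE, index=False)

    config = {
        "horizon": params.horizon,
        "start_age": params.start_age,
        "sex": params.sex,
        "threshold": params.threshold,
        "bmi_change": params.effects.bmi_change,
        "cost_discount_rate": params.costs.discount_rate,
        "qaly_discount_rate": params.utilities.discount_rate,
        "utility_gain_per_bmi_unit": params.utilities.utility_gain_per_bmi_unit,
        "relative_risks": {
            "diabetes": params.relative_risks.diabetes,
            "stroke": params.relative_risks.stroke,
            "chd_young": params.relative_risks.chd_young,
            "chd_old": params.relative_risks.chd_old,
            "colon": params.relative_risks.colon,
            "diabetes_to_colon": params.relative_risks.diabetes_to_colon,
            "chd_age_cutoff": params.relative_risks.chd_age_cutoff,
        },
        "intervention_cost": {
            "pedometer": params.costs.pedometer,
            "staff": params.costs.staff,
            "admin": params.costs.admin,
            "manual": params.costs.manual,
            "pedometer_life": params.costs.pedometer_life,
            "pedometer_year_se": params.costs.pedometer_year_se,
            "other_year_se": params.costs.other_year_se,
        },
        "options": dataclasses.asdict(params.options),
    }
    with open(outdir / _CONFIG_FILE, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return outdir


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter bundle written by
    :func:`write_parameters`.

    Raises :class:`ParameterError` naming the first problem if any file is
    missing, a probability is out of range or a distribution family is
    unknown.
    """
    path = Path(path)
    if path.is_file():
        path = path.parent
    for fname in (_EPI_FILE, _EFFECTS_FILE, _COSTS_FILE, _UTILITIES_FILE, _CONFIG_FILE):
        if not (path / fname).exists():
            raise ParameterError(f"missing parameter file '{fname}' in {path}")

    epi = EpidemiologyTable.from_frame(pd.read_csv(path / _EPI_FILE))

    eff = pd.read_csv(path / _EFFECTS_FILE)
    for col in ("disease", "sex", "per_unit_reduction_pct", "se_pct"):
        if col not in eff.columns:
            raise ParameterError(f"effects table missing column '{col}'")
    per_unit = {
        (r.disease, r.sex): float(r.per_unit_reduction_pct) for r in eff.itertuples()
    }
    se_pct = {(r.disease, r.sex): float(r.se_pct) for r in eff.itertuples()}

    costs_df = pd.read_csv(path / _COSTS_FILE)
    state_costs = {
        r.state: (float(r.annual_cost_eur), float(r.se_eur))
        for r in costs_df.itertuples()
    }

    util_df = pd.read_csv(path / _UTILITIES_FILE)
    utilities = {r.state: (float(r.utility), float(r.se)) for r in util_df.itertuples()}

    with open(path / _CONFIG_FILE) as fh:
        config = yaml.safe_load(fh)

    rr_cfg = config.get("relative_risks", {})
    ic = config.get("intervention_cost", {})
    params = ParameterSet(
        epidemiology=epi,
        relative_risks=RelativeRiskSet(**rr_cfg),
        effects=EffectSpec(per_unit, se_pct, float(config.get("bmi_change", 0.20))),
        costs=CostTable(
            state_costs,
            pedometer=float(ic.get("pedometer", 13.70)),
            staff=float(ic.get("staff", 20.57)),
            admin=float(ic.get("admin", 0.48)),
            manual=float(ic.get("manual", 0.25)),
            pedometer_life=int(ic.get("pedometer_life", 5)),
            pedometer_year_se=float(ic.get("pedometer_year_se", 3.50)),
            other_year_se=float(ic.get("other_year_se", 2.13)),
            discount_rate=float(config.get("cost_discount_rate", 0.03)),
        ),
        utilities=UtilityTable(
            utilities,
            discount_rate=float(config.get("qaly_discount_rate", 0.015)),
            utility_gain_per_bmi_unit=float(
                config.get("utility_gain_per_bmi_unit", 0.021)
            ),
        ),
        horizon=int(config.get("horizon", 20)),
        start_age=(None if config.get("start_age") is None else int(config["start_age"])),
        sex=config.get("sex", "men"),
        threshold=float(config.get("threshold", 30_000.0)),
        options=ModelOptions(**config.get("options", {})),
    )

    for r in util_df.itertuples():
        if r.distribution not in (*DISTRIBUTION_FAMILIES, "point"):
            raise ParameterError(
                f"utility '{r.state}': unknown distribution family '{r.distribution}'"
            )
    issues = validate(params)
    if issues:
        raise ParameterError("invalid parameter bundle: " + "; ".join(issues))
    return params


def to_json(params: ParameterSet) -> str:
    """JSON export of the full parameter set for archival."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(type(obj))

    payload = {
        "epidemiology": {
            "bands": [[b.lower, b.upper] for b in params.epidemiology.bands],
            "values": params.epidemiology.values,
        },
        "relative_risks": dataclasses.asdict(params.relative_risks),
        "effects": {
            "per_unit_pct": {f"{d}:{s}": v for (d, s), v in params.effects.per_unit_pct.items()},
            "se_pct": {f"{d}:{s}": v for (d, s), v in params.effects.se_pct.items()},
            "bmi_change": params.effects.bmi_change,
        },
        "costs": dataclasses.asdict(params.costs),
        "utilities": dataclasses.asdict(params.utilities),
        "horizon": params.horizon,
        "start_age": params.start_age,
        "sex": params.sex,
        "threshold": params.threshold,
        "options": dataclasses.asdict(params.options),
    }
    return json.dumps(payload, default=_default, indent=2)
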