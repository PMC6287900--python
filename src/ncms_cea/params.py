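"""Model inputs as validated domain types, with YAML/CSV round-trip I/O.

The parameter surface mirrors the published input table of the NCMS
cost-effectiveness model: uncertain scalars carry (base, low, high) bounds
used by the sensitivity machinery, and the two age/sex schedules (background
mortality, hypertension incidence) are loaded from CSV files with header
``age,male,female``.

All monetary values are 2013 international dollars (Int$) throughout; the
PPP rate (CNY per Int$) is stored for reporting only and never enters the
model arithmetic.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
MORTALITY_BANDS = ("20-44", "45-59", "60+")
LABOR_BANDS = ("30-49", "50+")

#: Bundled fixture file names (inside ``ncms_cea/fixtures``). The schedules
#: are synthetic stand-ins for the unpublished national life table and
#: hypertension-incidence table; see the synthetic module.
TABLE1_FIXTURE = "table1.yaml"
MORTALITY_FIXTURE = "mortality_synthetic.csv"
INCIDENCE_FIXTURE = "htn_incidence_synthetic.csv"


class ParameterValidationError(ValueError):
    """A model input violates one of its documented invariants."""

    def __init__(self, field_name: str, message: str) -> None:
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class ParameterParseError(ValueError):
    """A configuration file is malformed (missing or mistyped key)."""


@dataclass
class UncertainValue:
    """A scalar input with its most-likely value and low/high bounds.

    The base value is the point estimate used in the base case; low/high are
    the bounds used for one-way sensitivity analyses and as the support of
    the triangular distribution in the probabilistic sensitivity analysis.
    """

    base: float
    low: float
    high: float

    def validate(self, name: str = "UncertainValue") -> None:
        if not (self.low <= self.base <= self.high):
            raise ParameterValidationError(
                name, f"requires low <= base <= high, got ({self.low}, {self.base}, {self.high})"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    def scaled(self, k: float) -> "UncertainValue":
        """Multiply all three values by a positive factor (preserves order)."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return UncertainValue(self.base * k, self.low * k, self.high * k)


def mortality_band(age: int) -> str:
    """Band used by the mortality marginal effects (channel-specific)."""
    if age < 45:
        return "20-44"
    if age < 60:
        return "45-59"
    return "60+"


def labor_band(age: int) -> str | None:
    """Band used by the labor-productivity benefit; None below age 30."""
    if age < 30:
        return None
    if age < 50:
        return "30-49"
    return "50+"


@dataclass
class AgeSchedule:
    """Map from integer age to an annual probability, for one sex."""

    sex: str
    entries: dict[int, float]

    kind: str = "probability"

    def validate(self, name: str, start_age: int = 20, end_age: int = 100) -> None:
        if self.sex not in SEXES:
            raise ParameterValidationError(name, f"sex must be one of {SEXES}, got {self.sex!r}")
        for age in range(start_age, end_age):
            if age not in self.entries:
                raise ParameterValidationError(name, f"age {age} missing from schedule")
        for age, p in self.entries.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterValidationError(name, f"value {p} at age {age} outside [0, 1]")

    def probability(self, age: int) -> float:
        return self.entries[age]

    def values(self, start_age: int, end_age: int) -> list[float]:
        return [self.entries[a] for a in range(start_age, end_age)]


class MortalitySchedule(AgeSchedule):
    """Annual death probabilities q(age) from a period life table.

    Values are interpreted as probabilities (qx), not central death rates;
    everyone still alive at the terminal model age exits the cohort.
    """


class HypertensionIncidence(AgeSchedule):
    """Annual probability of a normotensive person becoming hypertensive.

    The published supplementary table reports the age- and sex-specific
    "likelihood of hypertension"; this implementation treats the schedule as
    annual incidence, which is what an irreversible-state Markov transition
    consumes.
    """


@dataclass
class EffectParams:
    """Intervention effects: mortality marginal effects and hypertension RR.

    ``mortality_effects`` maps (sex, band) to a signed change in the annual
    death rate per 1,000 population; negative values mean the insurance
    scheme lowers mortality. ``rr_hypertension`` multiplies the annual
    incidence of hypertension in the intervention arm.
    """

    rr_hypertension: UncertainValue
    mortality_effects: dict[tuple[str, str], UncertainValue]

    def validate(self) -> None:
        self.rr_hypertension.validate("effects.rr_hypertension")
        if self.rr_hypertension.low <= 0:
            raise ParameterValidationError("effects.rr_hypertension", "risk ratio must be > 0")
        expected = {(s, b) for s in SEXES for b in MORTALITY_BANDS}
        if set(self.mortality_effects) != expected:
            missing = expected - set(self.mortality_effects)
            extra = set(self.mortality_effects) - expected
            raise ParameterValidationError(
                "effects.mortality_effects",
                f"need exactly the six sex*band entries; missing={sorted(missing)} extra={sorted(extra)}",
            )
        for (sex, band), uv in self.mortality_effects.items():
            uv.validate(f"effects.mortality_effects[{sex},{band}]")


@dataclass
class Utilities:
    """Health-related quality-of-life weights for the three states."""

    u_normotensive: UncertainValue
    u_hypertensive: UncertainValue
    u_dead: float = 0.0

    def validate(self) -> None:
        self.u_normotensive.validate("utilities.u_normotensive")
        self.u_hypertensive.validate("utilities.u_hypertensive")
        if not (0.0 <= self.u_hypertensive.base <= self.u_normotensive.base <= 1.0):
            raise ParameterValidationError(
                "utilities", "requires 0 <= u_hypertensive <= u_normotensive <= 1"
            )
        if self.u_dead != 0.0:
            raise ParameterValidationError("utilities.u_dead", "death utility is fixed at 0")


@dataclass
class CostParams:
    """Program cost inputs, Int$ per person-year.

    ``he1`` is total health expenditure per rural resident after the program;
    the pre-program level is recovered as he1/(1+g) where g is the
    expenditure growth rate attributed to the program.
    """

    he1: UncertainValue
    growth_rate: UncertainValue
    htn_annual_cost: UncertainValue
    ppp_rate: float = 3.55

    def validate(self) -> None:
        self.he1.validate("costs.he1")
        self.growth_rate.validate("costs.growth_rate")
        self.htn_annual_cost.validate("costs.htn_annual_cost")
        if self.he1.low <= 0:
            raise ParameterValidationError("costs.he1", "expenditure must be > 0")
        if self.growth_rate.low <= -1:
            raise ParameterValidationError("costs.growth_rate", "growth rate must be > -1")
        if self.htn_annual_cost.low < 0:
            raise ParameterValidationError("costs.htn_annual_cost", "cost must be >= 0")
        if self.ppp_rate <= 0:
            raise ParameterValidationError("costs.ppp_rate", "PPP rate must be > 0")


@dataclass
class LaborParams:
    """Labor-productivity monetization inputs.

    The program's labor benefit per alive person-year in band b is
    ``d_offfarm_p[b] * annual_wage + d_farm_hours[b] * agri_hourly``;
    ages below 30 receive no labor benefit (no published effect there).
    """

    baseline_offfarm_p: float
    d_offfarm_p: dict[str, UncertainValue]
    d_farm_hours: dict[str, UncertainValue]
    annual_wage: UncertainValue
    agri_hourly: UncertainValue

    def validate(self) -> None:
        for mapping, label in ((self.d_offfarm_p, "d_offfarm_p"), (self.d_farm_hours, "d_farm_hours")):
            if set(mapping) != set(LABOR_BANDS):
                raise ParameterValidationError(
                    f"labor.{label}", f"bands must be exactly {LABOR_BANDS}, got {sorted(mapping)}"
                )
            for band, uv in mapping.items():
                uv.validate(f"labor.{label}[{band}]")
        self.annual_wage.validate("labor.annual_wage")
        self.agri_hourly.validate("labor.agri_hourly")
        for name, uv in (("annual_wage", self.annual_wage), ("agri_hourly", self.agri_hourly)):
            if uv.low < 0:
                raise ParameterValidationError(f"labor.{name}", "monetary value must be >= 0")
        if not (0.0 <= self.baseline_offfarm_p <= 1.0):
            raise ParameterValidationError("labor.baseline_offfarm_p", "probability outside [0, 1]")


@dataclass
class EconSettings:
    """Discounting, WTP threshold inputs, cohort ages and sex weighting."""

    discount_rate: UncertainValue
    gdp_per_capita: float
    wtp_multiplier: float = 3.0
    start_age: int = 20
    end_age: int = 100
    sex_weights: dict[str, float] = field(default_factory=lambda: {"male": 0.5, "female": 0.5})

    def validate(self) -> None:
        self.discount_rate.validate("econ.discount_rate")
        if self.discount_rate.low < 0:
            raise ParameterValidationError("econ.discount_rate", "discount rate must be >= 0")
        if self.gdp_per_capita < 0:
            raise ParameterValidationError("econ.gdp_per_capita", "GDP must be >= 0")
        if not self.start_age < self.end_age:
            raise ParameterValidationError("econ", "start_age must be < end_age")
        if set(self.sex_weights) != set(SEXES):
            raise ParameterValidationError("econ.sex_weights", f"keys must be {SEXES}")
        total = sum(self.sex_weights.values())
        if abs(total - 1.0) > 1e-9 or any(w < 0 for w in self.sex_weights.values()):
            raise ParameterValidationError("econ.sex_weights", f"weights must be >= 0 and sum to 1, got {total}")


@dataclass
class ParameterSet:
    """Complete, validated input set for the two-arm cohort model."""

    mortality: dict[str, MortalitySchedule]
    incidence: dict[str, HypertensionIncidence]
    effects: EffectParams
    utilities: Utilities
    costs: CostParams
    labor: LaborParams
    econ: EconSettings

    def validate(self) -> None:
        self.econ.validate()
        for sex in SEXES:
            if sex not in self.mortality:
                raise ParameterValidationError("mortality", f"schedule for {sex} missing")
            if sex not in self.incidence:
                raise ParameterValidationError("incidence", f"schedule for {sex} missing")
            self.mortality[sex].validate(f"mortality[{sex}]", self.econ.start_age, self.econ.end_age)
            self.incidence[sex].validate(f"incidence[{sex}]", self.econ.start_age, self.econ.end_age)
        self.effects.validate()
        self.utilities.validate()
        self.costs.validate()
        self.labor.validate()

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def wtp_threshold(econ: EconSettings) -> float:
    """Willingness-to-pay threshold, Int$ per QALY (multiplier x GDP/capita)."""
    if econ.gdp_per_capita < 0:
        raise ParameterValidationError("econ.gdp_per_capita", "GDP must be >= 0")
    return econ.wtp_multiplier * econ.gdp_per_capita


# ---------------------------------------------------------------------------
# I/O


def _uv(node: object, key: str) -> UncertainValue:
    if isinstance(node, (int, float)):
        v = float(node)
        return UncertainValue(v, v, v)
    if not isinstance(node, Mapping):
        raise ParameterParseError(f"{key}: expected mapping with base/low/high, got {node!r}")
    try:
        return UncertainValue(float(node["base"]), float(node["low"]), float(node["high"]))
    except KeyError as exc:
        raise ParameterParseError(f"{key}: missing sub-key {exc.args[0]!r}") from None
    except (TypeError, ValueError):
        raise ParameterParseError(f"{key}: base/low/high must be numeric, got {node!r}") from None


def _require(mapping: Mapping, key: str, context: str) -> object:
    if key not in mapping:
        raise ParameterParseError(f"missing key {context}.{key}" if context else f"missing key {key}")
    return mapping[key]


def _schedule_from_csv(path: Path, cls, name: str) -> dict[str, AgeSchedule]:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["age", "male", "female"]
    if list(df.columns) != expected:
        raise ParameterParseError(f"{name} schedule {path}: columns must be {expected}, got {list(df.columns)}")
    out = {}
    for sex in SEXES:
        entries = {int(a): float(v) for a, v in zip(df["age"], df[sex])}
        out[sex] = cls(sex=sex, entries=entries)
    return out


def _fixture_path(filename: str) -> Path:
    return Path(str(resources.files("ncms_cea").joinpath("fixtures", filename)))


def _resolve_schedule(cfg: Mapping, key: str, base_dir: Path, fallback: str) -> Path:
    schedules = cfg.get("schedules") or {}
    rel = schedules.get(key)
    if rel is None:
        warnings.warn(
            f"config has no schedules.{key}; falling back to bundled fixture {fallback}",
            stacklevel=3,
        )
        logger.warning("schedules.%s absent; using bundled fixture %s", key, fallback)
        return _fixture_path(fallback)
    path = Path(rel)
    return path if path.is_absolute() else base_dir / path


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Read a parameter configuration (YAML + schedule CSVs) and validate it.

    Schedule paths in the config are resolved relative to the config file;
    a missing schedule entry falls back to the bundled synthetic fixture
    with a logged warning.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParameterParseError(f"{config_path}: invalid YAML ({exc})") from exc
    if not isinstance(cfg, Mapping):
        raise ParameterParseError(f"{config_path}: top level must be a mapping")
    base_dir = config_path.parent

    eff = _require(cfg, "effects", "")
    mort_eff = _require(eff, "mortality_per_1000", "effects")
    effects = EffectParams(
        rr_hypertension=_uv(_require(eff, "rr_hypertension", "effects"), "effects.rr_hypertension"),
        mortality_effects={
            (sex, band): _uv(
                _require(_require(mort_eff, sex, "effects.mortality_per_1000"), band, f"effects.mortality_per_1000.{sex}"),
                f"effects.mortality_per_1000.{sex}.{band}",
            )
            for sex in SEXES
            for band in MORTALITY_BANDS
        },
    )

    util = _require(cfg, "utilities", "")
    utilities = Utilities(
        u_normotensive=_uv(_require(util, "normotensive", "utilities"), "utilities.normotensive"),
        u_hypertensive=_uv(_require(util, "hypertensive", "utilities"), "utilities.hypertensive"),
    )

    cost = _require(cfg, "costs", "")
    costs = CostParams(
        he1=_uv(_require(cost, "total_health_expenditure", "costs"), "costs.total_health_expenditure"),
        growth_rate=_uv(_require(cost, "growth_rate", "costs"), "costs.growth_rate"),
        htn_annual_cost=_uv(_require(cost, "htn_annual_cost", "costs"), "costs.htn_annual_cost"),
        ppp_rate=float(cost.get("ppp_rate", 3.55)),
    )

    lab = _require(cfg, "labor", "")
    labor = LaborParams(
        baseline_offfarm_p=float(_require(lab, "baseline_offfarm_p", "labor")),
        d_offfarm_p={b: _uv(_require(_require(lab, "d_offfarm_p", "labor"), b, "labor.d_offfarm_p"), f"labor.d_offfarm_p.{b}") for b in LABOR_BANDS},
        d_farm_hours={b: _uv(_require(_require(lab, "d_farm_hours", "labor"), b, "labor.d_farm_hours"), f"labor.d_farm_hours.{b}") for b in LABOR_BANDS},
        annual_wage=_uv(_require(lab, "annual_wage", "labor"), "labor.annual_wage"),
        agri_hourly=_uv(_require(lab, "agri_hourly", "labor"), "labor.agri_hourly"),
    )

    ec = _require(cfg, "econ", "")
    econ = EconSettings(
        discount_rate=_uv(_require(ec, "discount_rate", "econ"), "econ.discount_rate"),
        gdp_per_capita=float(_require(ec, "gdp_per_capita", "econ")),
        wtp_multiplier=float(ec.get("wtp_multiplier", 3.0)),
        start_age=int(ec.get("start_age", 20)),
        end_age=int(ec.get("end_age", 100)),
        sex_weights={k: float(v) for k, v in ec.get("sex_weights", {"male": 0.5, "female": 0.5}).items()},
    )

    mortality = _schedule_from_csv(
        _resolve_schedule(cfg, "mortality", base_dir, MORTALITY_FIXTURE), MortalitySchedule, "mortality"
    )
    incidence = _schedule_from_csv(
        _resolve_schedule(cfg, "incidence", base_dir, INCIDENCE_FIXTURE), HypertensionIncidence, "incidence"
    )

    p = ParameterSet(
        mortality=mortality,
        incidence=incidence,
        effects=effects,
        utilities=utilities,
        costs=costs,
        labor=labor,
        econ=econ,
    )
    p.validate()
    return p


def _uv_node(uv: UncertainValue) -> dict:
    return {"base": uv.base, "low": uv.low, "high": uv.high}


def save_parameters(p: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet so that :func:`load_parameters` reproduces it.

    Writes the YAML config at ``path`` plus two schedule CSVs next to it
    (``<stem>_mortality.csv`` and ``<stem>_incidence.csv``).
    """
    p.validate()
    path = Path(path)
    mort_name = f"{path.stem}_mortality.csv"
    inc_name = f"{path.stem}_incidence.csv"

    cfg = {
        "effects": {
            "mortality_per_1000": {
                sex: {band: _uv_node(p.effects.mortality_effects[(sex, band)]) for band in MORTALITY_BANDS}
                for sex in SEXES
            },
            "rr_hypertension": _uv_node(p.effects.rr_hypertension),
        },
        "utilities": {
            "normotensive": _uv_node(p.utilities.u_normotensive),
            "hypertensive": _uv_node(p.utilities.u_hypertensive),
        },
        "costs": {
            "total_health_expenditure": _uv_node(p.costs.he1),
            "growth_rate": _uv_node(p.costs.growth_rate),
            "htn_annual_cost": _uv_node(p.costs.htn_annual_cost),
            "ppp_rate": p.costs.ppp_rate,
        },
        "labor": {
            "baseline_offfarm_p": p.labor.baseline_offfarm_p,
            "d_offfarm_p": {b: _uv_node(p.labor.d_offfarm_p[b]) for b in LABOR_BANDS},
            "d_farm_hours": {b: _uv_node(p.labor.d_farm_hours[b]) for b in LABOR_BANDS},
            "annual_wage": _uv_node(p.labor.annual_wage),
            "agri_hourly": _uv_node(p.labor.agri_hourly),
        },
        "econ": {
            "discount_rate": _uv_node(p.econ.discount_rate),
            "gdp_per_capita": p.econ.gdp_per_capita,
            "wtp_multiplier": p.econ.wtp_multiplier,
            "start_age": p.econ.start_age,
            "end_age": p.econ.end_age,
            "sex_weights": dict(p.econ.sex_weights),
        },
        "schedules": {"mortality": mort_name, "incidence": inc_name},
    }

    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)

    for name, schedules in ((mort_name, p.mortality), (inc_name, p.incidence)):
        ages = sorted(schedules["male"].entries)
        df = pd.DataFrame(
            {
                "age": ages,
                "male": [schedules["male"].entries[a] for a in ages],
                "female": [schedules["female"].entries[a] for a in ages],
            }
        )
        df.to_csv(path.parent / name, index=False, float_format="%.17g")


def bundled_config_path() -> Path:
    """Path of the bundled base-case configuration (published input table)."""
    return _fixture_path(TABLE1_FIXTURE)


def load_bundled_parameters() -> ParameterSet:
    """The bundled base-case ParameterSet (synthetic schedules)."""
    return load_parameters(bundled_config_path())


def iter_uncertain(p: ParameterSet) -> Iterator[tuple[str, UncertainValue]]:
    """Stable enumeration of every uncertain scalar in the set.

    The order is fixed (documented here, relied upon by the PSA sampler):
    six mortality effects (male bands, then female bands), hypertension RR,
    utilities, costs, labor, discount rate.
    """
    for sex in SEXES:
        for band in MORTALITY_BANDS:
            yield f"mortality_effect.{sex}.{band}", p.effects.mortality_effects[(sex, band)]
    yield "rr_hypertension", p.effects.rr_hypertension
    yield "u_normotensive", p.utilities.u_normotensive
    yield "u_hypertensive", p.utilities.u_hypertensive
    yield "total_health_expenditure", p.costs.he1
    yield "growth_rate", p.costs.growth_rate
    yield "htn_annual_cost", p.costs.htn_annual_cost
    for band in LABOR_BANDS:
        yield f"d_offfarm_p.{band}", p.labor.d_offfarm_p[band]
    for band in LABOR_BANDS:
        yield f"d_farm_hours.{band}", p.labor.d_farm_hours[band]
    yield "annual_wage", p.labor.annual_wage
    yield "agri_hourly", p.labor.agri_hourly
    yield "discount_rate", p.econ.discount_rate


def parameter_ids(p: ParameterSet) -> list[str]:
    return [name for name, _ in iter_uncertain(p)]


def get_uncertain(p: ParameterSet, param_id: str) -> UncertainValue:
    for name, uv in iter_uncertain(p):
        if name == param_id:
            return uv
    raise KeyError(f"unknown parameter id {param_id!r}; known ids: {parameter_ids(p)}")


def with_values(p: ParameterSet, values: Mapping[str, float]) -> ParameterSet:
    """A deep copy of ``p`` with the base of each named parameter replaced.

    Bounds are left untouched so the result remains a valid ParameterSet for
    any value inside [low, high]; values outside the bounds widen them (used
    nowhere by the shipped analyses, but keeps the copy valid).
    """
    q = p.copy()
    lookup = dict(iter_uncertain(q))
    for param_id, value in values.items():
        if param_id not in lookup:
            raise KeyError(f"unknown parameter id {param_id!r}")
        uv = lookup[param_id]
        uv.base = float(value)
        uv.low = min(uv.low, uv.base)
        uv.high = max(uv.high, uv.base)
    q.validate()
    return q
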