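"""Three-state annual-cycle Markov cohort model for one arm and one sex.

States are normotensive, hypertensive (absorbing until death) and dead
(absorbing). Each one-year cycle applies death first — with a probability
that is identical in both living states, since hypertension carries no
excess mortality in this model — then hypertension onset among survivors.
Rewards (utilities and costs) accrue on start-of-cycle occupancies and are
discounted by (1+r)^-t with t = 0 at the cohort's entry age; both choices
are isolated in :class:`Conventions` so alternative accounting conventions
are a keyword away.

Because the death probability is state-independent, the occupancy recursion
has a closed form: the alive fraction is the running product of survival
probabilities, and the still-normotensive fraction is the running product of
surviving *and* escaping onset. The engine exploits this; the generic
transition-matrix formulation serves as an independent oracle in the tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import LaborParams, ParameterSet, labor_band, mortality_band

COST_COMPONENTS = ("extra_health_expenditure", "htn_medical", "labor_benefit")


class Arm(enum.Enum):
    """The two strategies compared: insured (NCMS) versus uninsured."""

    NCMS = "NCMS"
    CONTROL = "no-NCMS"


@dataclass(frozen=True)
class Conventions:
    """Accounting conventions the published model leaves unstated.

    half_cycle
        If True, rewards use the average of start- and end-of-cycle
        occupancies (a standard half-cycle correction); default False,
        i.e. rewards on start-of-cycle occupancies.
    discount_age_offset
        Added to the cycle index in the discount exponent. 0 discounts from
        model entry (age 20); ``start_age`` (20) reproduces discounting from
        birth. The ICER is invariant to this choice since the same factor
        multiplies costs and QALYs.
    """

    half_cycle: bool = False
    discount_age_offset: float = 0.0


@dataclass
class CohortTrace:
    """Per-cycle state occupancies (cohort fractions) for one arm and sex."""

    ages: np.ndarray
    occ_normotensive: np.ndarray
    occ_hypertensive: np.ndarray
    occ_dead: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.ages)),
                "age": self.ages,
                "occ_normotensive": self.occ_normotensive,
                "occ_hypertensive": self.occ_hypertensive,
                "occ_dead": self.occ_dead,
            }
        )


@dataclass
class ArmOutcome:
    """Discounted lifetime totals for one arm (possibly sex-averaged)."""

    cost_total: float
    qalys: float
    cost_components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cost_components:
            gap = abs(self.cost_total - sum(self.cost_components.values()))
            if gap > 1e-9 * max(1.0, abs(self.cost_total)):
                raise ValueError(f"cost components do not sum to total (gap {gap})")


def adjusted_mortality(q: float, effect_per_1000: float) -> float:
    """Annual death probability after adding a signed per-1,000 rate change."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"death probability {q} outside [0, 1]")
    return min(max(q + effect_per_1000 / 1000.0, 0.0), 1.0)


def adjusted_incidence(p: float, rr: float, arm: Arm) -> float:
    """Annual hypertension onset probability; RR applies in the NCMS arm only."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"incidence {p} outside [0, 1]")
    if rr <= 0:
        raise ValueError("risk ratio must be > 0")
    if arm is Arm.CONTROL:
        return p
    return min(max(rr * p, 0.0), 1.0)


def cost_decomposition(he1: float, g: float) -> float:
    """Per-person annual expenditure increase attributed to the program.

    With post-program expenditure he1 and attributable growth rate g, the
    pre-program level is he1/(1+g), so the increment is he1 - he1/(1+g).
    """
    if he1 <= 0:
        raise ValueError("he1 must be > 0")
    if g <= -1:
        raise ValueError("growth rate must be > -1")
    return he1 - he1 / (1.0 + g)


def labor_gain(age: int, labor: LaborParams) -> float:
    """Monetized annual labor-productivity benefit per alive person, Int$.

    Off-farm participation gains are valued at the annual wage and extra
    agricultural hours at the agricultural hourly income; no benefit below
    age 30 (no published effect for that band).
    """
    band = labor_band(age)
    if band is None:
        return 0.0
    return (
        labor.d_offfarm_p[band].base * labor.annual_wage.base
        + labor.d_farm_hours[band].base * labor.agri_hourly.base
    )


def _transition_arrays(p: ParameterSet, arm: Arm, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ages = np.arange(p.econ.start_age, p.econ.end_age)
    q = np.array([p.mortality[sex].probability(int(a)) for a in ages])
    inc = np.array([p.incidence[sex].probability(int(a)) for a in ages])
    if arm is Arm.NCMS:
        eff = np.array(
            [p.effects.mortality_effects[(sex, mortality_band(int(a)))].base for a in ages]
        )
        q = np.clip(q + eff / 1000.0, 0.0, 1.0)
        inc = np.clip(p.effects.rr_hypertension.base * inc, 0.0, 1.0)
    return ages, q, inc


def run_cohort(
    p: ParameterSet,
    arm: Arm,
    sex: str,
    conventions: Conventions = Conventions(),
) -> tuple[CohortTrace, ArmOutcome]:
    """Run the cohort through all cycles and accumulate discounted rewards.

    Returns the per-cycle trace together with the lifetime outcome. Cycle t
    covers ages start_age+t; everyone alive at end_age exits with no
    terminal reward.
    """
    p.validate()
    ages, q, inc = _transition_arrays(p, arm, sex)
    n = len(ages)

    # Death is state-independent, so alive and never-hypertensive fractions
    # are running products; occupancies indexed 0..n (start of each cycle
    # plus the exit point).
    alive = np.concatenate(([1.0], np.cumprod((1.0 - q))))
    occ_n = np.concatenate(([1.0], np.cumprod((1.0 - q) * (1.0 - inc))))
    occ_h = alive - occ_n
    occ_d = 1.0 - alive

    if conventions.half_cycle:
        w_n = 0.5 * (occ_n[:-1] + occ_n[1:])
        w_h = 0.5 * (occ_h[:-1] + occ_h[1:])
    else:
        w_n = occ_n[:-1]
        w_h = occ_h[:-1]
    w_alive = w_n + w_h

    r = p.econ.discount_rate.base
    t = np.arange(n, dtype=float) + conventions.discount_age_offset
    disc = (1.0 + r) ** (-t)

    u_n = p.utilities.u_normotensive.base
    u_h = p.utilities.u_hypertensive.base
    qalys = float(np.sum(disc * (w_n * u_n + w_h * u_h)))

    htn_medical = float(np.sum(disc * w_h * p.costs.htn_annual_cost.base))
    if arm is Arm.NCMS:
        dhe = cost_decomposition(p.costs.he1.base, p.costs.growth_rate.base)
        extra_he = float(np.sum(disc * w_alive * dhe))
        gains = np.array([labor_gain(int(a), p.labor) for a in ages])
        labor_benefit = -float(np.sum(disc * w_alive * gains))
    else:
        extra_he = 0.0
        labor_benefit = 0.0

    components = {
        "extra_health_expenditure": extra_he,
        "htn_medical": htn_medical,
        "labor_benefit": labor_benefit,
    }
    outcome = ArmOutcome(cost_total=sum(components.values()), qalys=qalys, cost_components=components)
    trace = CohortTrace(
        ages=ages,
        occ_normotensive=occ_n[:-1],
        occ_hypertensive=occ_h[:-1],
        occ_dead=occ_d[:-1],
    )
    return trace, outcome


def run_arm(p: ParameterSet, arm: Arm, conventions: Conventions = Conventions()) -> ArmOutcome:
    """Sex-weighted lifetime outcome for one arm (weights from EconSettings)."""
    total_cost = 0.0
    total_qalys = 0.0
    components = {k: 0.0 for k in COST_COMPONENTS}
    for sex, weight in p.econ.sex_weights.items():
        _, outcome = run_cohort(p, arm, sex, conventions)
        total_cost += weight * outcome.cost_total
        total_qalys += weight * outcome.qalys
        for k in COST_COMPONENTS:
            components[k] += weight * outcome.cost_components[k]
    return ArmOutcome(cost_total=total_cost, qalys=total_qalys, cost_components=components)


def run_both_arms(
    p: ParameterSet, conventions: Conventions = Conventions()
) -> dict[Arm, ArmOutcome]:
    return {arm: run_arm(p, arm, conventions) for arm in Arm}


def export_trace(
    p: ParameterSet, arm: Arm, sex: str, conventions: Conventions = Conventions()
) -> pd.DataFrame:
    """Trace plus per-cycle discounted rewards, ready for CSV export."""
    trace, _ = run_cohort(p, arm, sex, conventions)
    df = trace.to_frame()
    r = p.econ.discount_rate.base
    disc = (1.0 + r) ** (-(df["cycle"].to_numpy(dtype=float) + conventions.discount_age_offset))
    w_n = df["occ_normotensive"].to_numpy()
    w_h = df["occ_hypertensive"].to_numpy()
    w_alive = w_n + w_h
    df["qaly_disc"] = disc * (w_n * p.utilities.u_normotensive.base + w_h * p.utilities.u_hypertensive.base)
    df["cost_disc_htn_medical"] = disc * w_h * p.costs.htn_annual_cost.base
    if arm is Arm.NCMS:
        dhe = cost_decomposition(p.costs.he1.base, p.costs.growth_rate.base)
        df["cost_disc_extra_health_expenditure"] = disc * w_alive * dhe
        gains = np.array([labor_gain(int(a), p.labor) for a in df["age"]])
        df["cost_disc_labor_benefit"] = -disc * w_alive * gains
    else:
        df["cost_disc_extra_health_expenditure"] = 0.0
        df["cost_disc_labor_benefit"] = 0.0
    df["cost_disc_total"] = (
        df["cost_disc_htn_medical"]
        + df["cost_disc_extra_health_expenditure"]
        + df["cost_disc_labor_benefit"]
    )
    return df
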