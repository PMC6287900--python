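"""Shared fixtures: bundled parameters, miniature models, matrix oracle."""

from __future__ import annotations

import numpy as np
import pytest

from ncms_cea.engine import Arm
from ncms_cea.params import (
    CostParams,
    EconSettings,
    EffectParams,
    HypertensionIncidence,
    LaborParams,
    MortalitySchedule,
    ParameterSet,
    UncertainValue,
    Utilities,
    iter_uncertain,
    load_bundled_parameters,
    mortality_band,
)


def uv(base: float, low: float | None = None, high: float | None = None) -> UncertainValue:
    if low is None:
        low = base
    if high is None:
        high = base
    return UncertainValue(base, low, high)


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    return load_bundled_parameters()


def make_mini_params(
    n_cycles: int = 3,
    q: float = 0.1,
    incidence: float = 0.2,
    u_n: float = 1.0,
    u_h: float = 0.9,
    extra_he: float = 100.0,
    htn_cost: float = 50.0,
    labor: float = 0.0,
    r: float = 0.0,
    rr: float = 1.0,
    mortality_effect: float = 0.0,
) -> ParameterSet:
    """A flat-schedule miniature model, hand-checkable by matrix powering.

    ``extra_he`` is realised through he1/growth such that the per-alive
    increment equals it exactly (he1 = 2*extra_he, g = 1). A nonzero
    ``labor`` value applies to every age (bands still matter only via
    engine.labor_gain, so ages must be >= 30 for it to bite; the miniature
    starts at 50 to keep one band).
    """
    start = 50
    end = start + n_cycles
    ages = range(start, end)
    sched_m = {a: q for a in ages}
    return ParameterSet(
        mortality={
            "male": MortalitySchedule("male", dict(sched_m)),
            "female": MortalitySchedule("female", dict(sched_m)),
        },
        incidence={
            "male": HypertensionIncidence("male", {a: incidence for a in ages}),
            "female": HypertensionIncidence("female", {a: incidence for a in ages}),
        },
        effects=EffectParams(
            rr_hypertension=uv(rr),
            mortality_effects={
                (sex, band): uv(mortality_effect)
                for sex in ("male", "female")
                for band in ("20-44", "45-59", "60+")
            },
        ),
        utilities=Utilities(u_normotensive=uv(u_n), u_hypertensive=uv(u_h)),
        costs=CostParams(he1=uv(2 * extra_he) if extra_he else uv(1.0), growth_rate=uv(1.0) if extra_he else uv(0.0), htn_annual_cost=uv(htn_cost)),
        labor=LaborParams(
            baseline_offfarm_p=0.17,
            d_offfarm_p={"30-49": uv(0.0), "50+": uv(1.0) if labor else uv(0.0)},
            d_farm_hours={"30-49": uv(0.0), "50+": uv(0.0)},
            annual_wage=uv(labor),
            agri_hourly=uv(0.0),
        ),
        econ=EconSettings(
            discount_rate=uv(r, 0.0, max(r, 0.05)),
            gdp_per_capita=12353.0,
            start_age=start,
            end_age=end,
        ),
    )


def matrix_power_trace(p: ParameterSet, arm: Arm, sex: str) -> np.ndarray:
    """Independent oracle: explicit 3x3 transition-matrix products.

    State order (normotensive, hypertensive, dead); death applies first,
    with a state-independent probability, then onset among survivors.
    Returns start-of-cycle occupancies, shape (n_cycles, 3).
    """
    start, end = p.econ.start_age, p.econ.end_age
    occ = np.array([1.0, 0.0, 0.0])
    rows = [occ.copy()]
    for age in range(start, end - 1):
        q = p.mortality[sex].probability(age)
        inc = p.incidence[sex].probability(age)
        if arm is Arm.NCMS:
            q = min(max(q + p.effects.mortality_effects[(sex, mortality_band(age))].base / 1000.0, 0.0), 1.0)
            inc = min(max(p.effects.rr_hypertension.base * inc, 0.0), 1.0)
        m = np.array(
            [
                [(1 - q) * (1 - inc), (1 - q) * inc, q],
                [0.0, 1 - q, q],
                [0.0, 0.0, 1.0],
            ]
        )
        occ = occ @ m
        rows.append(occ.copy())
    return np.array(rows)


def degenerate_except(p: ParameterSet, keep: set[str]) -> ParameterSet:
    """Collapse every uncertain scalar not in ``keep`` to its base value."""
    q = p.copy()
    for name, u in iter_uncertain(q):
        if name not in keep:
            u.low = u.high = u.base
    q.validate()
    return q
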