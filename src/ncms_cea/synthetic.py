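"""Synthetic demographic schedules and randomized parameter sets.

The published model consumes two external schedules — a national period
life table and an age/sex hypertension schedule — that live in an
unpublished supplement. This module generates parametric stand-ins with the
qualitative structure the analysis assumes: Gompertz–Makeham mortality
(exponentially age-increasing hazard over a constant background) and a
logistic age-increasing hypertension incidence curve, with a multiplicative
female/male hazard gap. Defaults are calibrated so remaining life
expectancy at age 20 lands in the 50–60 year band plausible for rural
China circa 2013.

It also draws randomized but always-valid parameter sets around the
published input table, for property testing every downstream module with
zero external files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import params as pm
from .params import (
    HypertensionIncidence,
    MortalitySchedule,
    ParameterSet,
    UncertainValue,
    load_bundled_parameters,
    save_parameters,
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the synthetic mortality and incidence generators.

    gompertz_lambda
        Age-independent (Makeham) background hazard, per year.
    gompertz_alpha, gompertz_beta
        Level and slope of the exponential (Gompertz) hazard term
        ``alpha * exp(beta * age)``.
    incidence_max, incidence_midpoint, incidence_steepness
        Logistic curve for annual hypertension onset probability:
        plateau level, age of half-plateau, and slope.
    sex_gap
        Multiplicative female/male hazard ratio (< 1: women die later).
    """

    gompertz_lambda: float = 1e-4
    gompertz_alpha: float = 6e-5
    gompertz_beta: float = 0.092
    incidence_max: float = 0.035
    incidence_midpoint: float = 55.0
    incidence_steepness: float = 0.07
    sex_gap: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gompertz_lambda < 0 or self.gompertz_alpha <= 0 or self.gompertz_beta <= 0:
            raise ValueError("Gompertz-Makeham parameters must satisfy lambda >= 0, alpha > 0, beta > 0")
        if not 0.0 <= self.incidence_max <= 1.0:
            raise ValueError("incidence_max must lie in [0, 1]")
        if self.incidence_steepness < 0:
            raise ValueError("incidence_steepness must be >= 0")
        if self.sex_gap <= 0:
            raise ValueError("sex_gap must be > 0")


DEFAULT_SPEC = SyntheticCohortSpec()


def generate_life_table(
    spec: SyntheticCohortSpec = DEFAULT_SPEC,
    sex: str = "male",
    start_age: int = 20,
    end_age: int = 100,
) -> MortalitySchedule:
    """Annual death probabilities q(age) = 1 - exp(-hazard(age)).

    The hazard is ``lambda + alpha * exp(beta * age)``, multiplied by
    ``sex_gap`` for females. Probabilities are strictly increasing in age
    and strictly inside (0, 1); parameter combinations whose hazard
    overflows before the terminal age are rejected.
    """
    ages = np.arange(start_age, end_age)
    hazard = spec.gompertz_lambda + spec.gompertz_alpha * np.exp(spec.gompertz_beta * ages)
    if sex == "female":
        hazard = spec.sex_gap * hazard
    elif sex != "male":
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    q = 1.0 - np.exp(-hazard)
    if not np.all(np.isfinite(q)) or np.any(q >= 1.0):
        raise ValueError("Gompertz-Makeham parameters imply q >= 1 before the terminal age")
    return MortalitySchedule(sex=sex, entries={int(a): float(v) for a, v in zip(ages, q)})


def generate_incidence(
    spec: SyntheticCohortSpec = DEFAULT_SPEC,
    sex: str = "male",
    start_age: int = 20,
    end_age: int = 100,
) -> HypertensionIncidence:
    """Logistic annual hypertension onset probability, increasing in age.

    p(age) = max / (1 + exp(-steepness * (age - midpoint))); the same curve
    is used for both sexes (the sex split of the unpublished schedule is
    not reproducible).
    """
    if sex not in pm.SEXES:
        raise ValueError(f"sex must be one of {pm.SEXES}, got {sex!r}")
    ages = np.arange(start_age, end_age)
    p = spec.incidence_max / (1.0 + np.exp(-spec.incidence_steepness * (ages - spec.incidence_midpoint)))
    return HypertensionIncidence(sex=sex, entries={int(a): float(v) for a, v in zip(ages, p)})


def synthesize_parameter_set(
    seed: int,
    jitter: float = 0.05,
    spec: SyntheticCohortSpec | None = None,
) -> ParameterSet:
    """A complete, valid ParameterSet with seeded multiplicative jitter.

    Starts from the bundled base-case configuration, replaces the schedules
    with synthetic ones, and multiplies each uncertain scalar's (base, low,
    high) triple by a common factor drawn uniformly from
    [1 - jitter, 1 + jitter] — a common positive factor preserves the
    low <= base <= high ordering for any sign pattern. ``jitter=0``
    reproduces the bundled values exactly. Deterministic in ``seed``.
    """
    if not 0.0 <= jitter < 1.0:
        raise ValueError("jitter must lie in [0, 1)")
    spec = spec if spec is not None else SyntheticCohortSpec(seed=seed)
    p = load_bundled_parameters()
    start, end = p.econ.start_age, p.econ.end_age
    p.mortality = {s: generate_life_table(spec, s, start, end) for s in pm.SEXES}
    p.incidence = {s: generate_incidence(spec, s, start, end) for s in pm.SEXES}

    rng = np.random.default_rng(seed)
    for _, uv in pm.iter_uncertain(p):
        k = float(rng.uniform(1.0 - jitter, 1.0 + jitter))
        scaled = UncertainValue(uv.base * k, uv.low * k, uv.high * k)
        uv.base, uv.low, uv.high = scaled.base, scaled.low, scaled.high
    # Keep utilities and the RR inside their structural bounds regardless of
    # the draw: probabilities/utilities may not exceed 1.
    for uv in (p.utilities.u_normotensive, p.utilities.u_hypertensive, p.effects.rr_hypertension):
        uv.base, uv.low, uv.high = (min(v, 1.0) for v in (uv.base, uv.low, uv.high))
    if p.utilities.u_hypertensive.base > p.utilities.u_normotensive.base:
        p.utilities.u_hypertensive, p.utilities.u_normotensive = (
            p.utilities.u_normotensive,
            p.utilities.u_hypertensive,
        )
    p.validate()
    return p


def life_expectancy(schedule: MortalitySchedule, start_age: int = 20, end_age: int = 100) -> float:
    """Remaining life expectancy at start_age implied by the schedule, years.

    Sum of start-of-year survival probabilities over the modelled ages
    (everyone alive at end_age is censored there, matching the model).
    """
    q = np.array(schedule.values(start_age, end_age))
    alive = np.concatenate(([1.0], np.cumprod(1.0 - q)))
    return float(np.sum(alive[:-1]))


def write_synthetic_inputs(out_dir: str | Path, seed: int = 0, jitter: float = 0.0) -> Path:
    """Write a synthetic configuration + schedule CSVs; returns config path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = synthesize_parameter_set(seed, jitter=jitter)
    config = out_dir / "parameters.yaml"
    save_parameters(p, config)
    return config
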