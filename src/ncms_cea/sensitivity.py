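"""One-way sensitivity analyses and Monte Carlo probabilistic sensitivity.

One-way analyses rerun the full two-arm model with a single parameter at
its low and high bound, all others at base. The PSA samples every uncertain
scalar independently from a triangular distribution with support [low, high]
and mode at the base value, reruns both arms per draw, and summarises the
incremental (cost, QALY) cloud: means, equal-tailed 95% percentile
intervals, cost-effectiveness-plane quadrant probabilities at the WTP
threshold, and the acceptability curve.

Sampling order is the stable parameter enumeration of
:func:`ncms_cea.params.iter_uncertain`; the generator is numpy's
``default_rng`` (PCG64), so a (parameter set, n, seed) triple reproduces a
PSA bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Arm, Conventions, run_both_arms
from .metrics import (
    Classification,
    IncrementalOutcome,
    classify,
    incremental,
    net_monetary_benefit,
)
from .params import ParameterSet, get_uncertain, iter_uncertain, with_values, wtp_threshold


@dataclass(frozen=True)
class TriangularSpec:
    """Triangular distribution on [low, high] with mode at the base value."""

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mode <= self.high):
            raise ValueError(f"invalid triangular spec ({self.low}, {self.mode}, {self.high})")


def sample_triangular(spec: TriangularSpec, u: float) -> float:
    """Inverse-CDF transform of a uniform(0,1) variate.

    For u at or below the mode's CDF mass (c-a)/(b-a) the left branch
    a + sqrt(u (b-a)(c-a)) applies, otherwise b - sqrt((1-u)(b-a)(b-c)).
    A degenerate spec (a = b) is a point mass.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    a, c, b = spec.low, spec.mode, spec.high
    if a == b:
        return a
    fc = (c - a) / (b - a)
    if u <= fc:
        return a + np.sqrt(u * (b - a) * (c - a))
    return b - np.sqrt((1.0 - u) * (b - a) * (b - c))


@dataclass
class OneWayResult:
    """Incremental outcomes with one parameter at its low and high bound."""

    parameter: str
    at_low: IncrementalOutcome
    at_high: IncrementalOutcome
    wtp: float

    def icer_span(self) -> float:
        """Width of the ICER interval; off-quadrant endpoints count as infinite."""

        def endpoint(o: IncrementalOutcome) -> float:
            if o.classification is Classification.DOMINANT:
                return -np.inf
            if o.d_qaly <= 0:
                return np.inf
            return o.icer
        lo, hi = endpoint(self.at_low), endpoint(self.at_high)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            return np.inf
        return abs(hi - lo)

    def nmb_span(self) -> float:
        """Width of the net-monetary-benefit interval at the WTP threshold.

        Always finite; breaks ties between parameters whose ICER span is
        infinite because an endpoint left the north-east quadrant.
        """
        return abs(net_monetary_benefit(self.at_high, self.wtp) - net_monetary_benefit(self.at_low, self.wtp))


def _evaluate(p: ParameterSet, wtp: float, conventions: Conventions) -> IncrementalOutcome:
    outcomes = run_both_arms(p, conventions)
    return incremental(outcomes[Arm.NCMS], outcomes[Arm.CONTROL], wtp)


def one_way(
    p: ParameterSet, param_id: str, conventions: Conventions = Conventions()
) -> OneWayResult:
    """Rerun the two-arm model with ``param_id`` at its low and high bound."""
    uv = get_uncertain(p, param_id)
    wtp = wtp_threshold(p.econ)
    return OneWayResult(
        parameter=param_id,
        at_low=_evaluate(with_values(p, {param_id: uv.low}), wtp, conventions),
        at_high=_evaluate(with_values(p, {param_id: uv.high}), wtp, conventions),
        wtp=wtp,
    )


def tornado(p: ParameterSet, conventions: Conventions = Conventions()) -> list[OneWayResult]:
    """One-way results for every uncertain parameter, widest ICER span first.

    Dominant/dominated endpoints make the ICER span infinite; such ties are
    broken by the (always finite) NMB span. Sorting is stable, so exact
    ties keep the parameter enumeration order.
    """
    results = [one_way(p, name, conventions) for name, _ in iter_uncertain(p)]
    return sorted(results, key=lambda r: (-r.icer_span(), -r.nmb_span()))


@dataclass
class PSAResult:
    """Monte Carlo PSA draws and their derived summaries."""

    n_draws: int
    seed: int
    wtp: float
    d_cost: np.ndarray
    d_qaly: np.ndarray
    mean_d_cost: float
    mean_d_qaly: float
    ci95_d_cost: tuple[float, float]
    ci95_d_qaly: tuple[float, float]
    quadrant_probs: dict[Classification, float]
    ceac: list[tuple[float, float]]

    @property
    def icer_of_means(self) -> float | None:
        """(mean Δcost)/(mean ΔQALY) — stable, unlike the mean of ratios."""
        if self.mean_d_qaly == 0:
            return None
        return self.mean_d_cost / self.mean_d_qaly


def quadrant_probabilities(
    draws: np.ndarray, wtp: float
) -> dict[Classification, float]:
    """Empirical fraction of draws in each cost-effectiveness-plane category.

    ``draws`` is an (n, 2) array of (d_cost, d_qaly) pairs.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one draw")
    labels = [classify(dc, dq, wtp) for dc, dq in draws]
    n = len(labels)
    return {cls: labels.count(cls) / n for cls in Classification}


def ceac(draws: np.ndarray, wtp_grid: np.ndarray) -> list[tuple[float, float]]:
    """Acceptability (fraction of draws with positive NMB) per WTP value."""
    draws = np.asarray(draws, dtype=float)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if draws.size == 0 or wtp_grid.size == 0:
        raise ValueError("draws and wtp grid must be nonempty")
    d_cost, d_qaly = draws[:, 0], draws[:, 1]
    return [
        (float(w), float(np.mean(w * d_qaly - d_cost > 0.0)))
        for w in wtp_grid
    ]


def default_wtp_grid(wtp: float, n_points: int = 41) -> np.ndarray:
    """Evenly spaced WTP grid from 0 to twice the threshold (inclusive)."""
    return np.linspace(0.0, 2.0 * wtp, n_points)


def run_psa(
    p: ParameterSet,
    n: int,
    seed: int,
    conventions: Conventions = Conventions(),
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Monte Carlo PSA: n draws from independent triangular distributions.

    Every uncertain scalar (including the discount rate) is sampled from
    Triangular(low, base, high); parameters with degenerate bounds collapse
    to their base value. Each draw reruns both arms and records the
    incremental pair.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p.validate()
    wtp = wtp_threshold(p.econ)
    names = [name for name, _ in iter_uncertain(p)]
    specs = [TriangularSpec(uv.low, uv.base, uv.high) for _, uv in iter_uncertain(p)]

    rng = np.random.default_rng(seed)
    u = rng.random((n, len(names)))

    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    for i in range(n):
        values = {name: sample_triangular(spec, u[i, j]) for j, (name, spec) in enumerate(zip(names, specs))}
        o = _evaluate(with_values(p, values), wtp, conventions)
        d_cost[i] = o.d_cost
        d_qaly[i] = o.d_qaly

    draws = np.column_stack([d_cost, d_qaly])
    grid = default_wtp_grid(wtp) if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    return PSAResult(
        n_draws=n,
        seed=seed,
        wtp=wtp,
        d_cost=d_cost,
        d_qaly=d_qaly,
        mean_d_cost=float(np.mean(d_cost)),
        mean_d_qaly=float(np.mean(d_qaly)),
        ci95_d_cost=(float(np.percentile(d_cost, 2.5)), float(np.percentile(d_cost, 97.5))),
        ci95_d_qaly=(float(np.percentile(d_qaly, 2.5)), float(np.percentile(d_qaly, 97.5))),
        quadrant_probs=quadrant_probabilities(draws, wtp),
        ceac=ceac(draws, grid),
    )
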