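"""Incremental cost-effectiveness metrics and classification.

The ICER is always computed on unrounded incremental values; rounding for
display happens in the reporting layer only (which is why a table can print
a ΔQALY of 0.01 next to an ICER that does not equal Δcost/0.01).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .engine import ArmOutcome


class Classification(enum.Enum):
    """Cost-effectiveness plane category at a given WTP threshold.

    QALY losses are pooled into one category regardless of cost sign,
    matching how the published analysis reports its quadrant probabilities.
    """

    DOMINANT = "dominant"
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    QALY_LOSS = "qaly_loss"


@dataclass
class IncrementalOutcome:
    """Incremental cost, effect, their ratio and its classification."""

    d_cost: float
    d_qaly: float
    icer: float | None
    classification: Classification


def classify(d_cost: float, d_qaly: float, wtp: float) -> Classification:
    """Classify an incremental pair against a willingness-to-pay threshold.

    The WTP boundary is inclusive: an ICER exactly at the threshold counts
    as cost-effective.
    """
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    if d_qaly <= 0:
        return Classification.QALY_LOSS
    if d_cost <= 0:
        return Classification.DOMINANT
    return Classification.COST_EFFECTIVE if d_cost / d_qaly <= wtp else Classification.NOT_COST_EFFECTIVE


def incremental(ncms: ArmOutcome, control: ArmOutcome, wtp: float) -> IncrementalOutcome:
    """Incremental outcome of the NCMS arm over the control arm."""
    d_cost = ncms.cost_total - control.cost_total
    d_qaly = ncms.qalys - control.qalys
    icer = d_cost / d_qaly if d_qaly != 0 else None
    return IncrementalOutcome(
        d_cost=d_cost,
        d_qaly=d_qaly,
        icer=icer,
        classification=classify(d_cost, d_qaly, wtp),
    )


def net_monetary_benefit(o: IncrementalOutcome, wtp: float) -> float:
    """NMB = wtp * ΔQALY − Δcost; positive iff acceptable at that WTP."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * o.d_qaly - o.d_cost


def icer_display(o: IncrementalOutcome) -> str:
    """Human-readable ICER: 'cost-saving' / 'dominated' for the off-quadrants."""
    if o.classification is Classification.DOMINANT:
        return "cost-saving"
    if o.d_qaly <= 0:
        return "dominated" if o.d_cost >= 0 else "less costly, fewer QALYs"
    if o.icer is None or not math.isfinite(o.icer):
        return "undefined"
    return f"{o.icer:,.0f}"
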