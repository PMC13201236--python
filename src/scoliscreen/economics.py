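"""Incremental cost-utility arithmetic: NMB, INMB, ICER and dominance.

Conventions: increments are screening minus no-screening; net monetary
benefit is QALY x WTP - cost; a strategy that is cheaper and no less
effective than its comparator dominates it, in which case the dominance
label supersedes the ICER.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .markov import ArmResult

__all__ = ["nmb", "compare", "ComparisonResult"]


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit ``qaly * wtp - cost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return qaly * wtp - cost


@dataclass(frozen=True)
class ComparisonResult:
    """Per-arm and incremental economics of screening vs. no screening."""

    cost_screen: float
    cost_none: float
    qaly_screen: float
    qaly_none: float
    wtp: float
    delta_cost: float
    delta_qaly: float
    nmb_screen: float
    nmb_none: float
    inmb: float
    icer: float | None
    dominance: str | None

    @property
    def icer_label(self) -> str:
        if self.dominance is not None:
            return self.dominance
        if self.icer is None:
            return "undefined"
        return f"{self.icer:.2f}"


def _classify(delta_cost: float, delta_qaly: float) -> tuple[float | None, str | None]:
    """ICER and dominance label for an increment.

    Returns ``(icer, label)`` where exactly one of the two is meaningful:
    dominance short-circuits ICER presentation.
    """
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return None, "equivalent"
    if delta_cost < 0.0 and delta_qaly >= 0.0:
        return None, "dominant"
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return None, "dominated"
    if delta_qaly == 0.0:  # delta_cost > 0 here
        return None, "not cost-effective at any WTP"
    return delta_cost / delta_qaly, None


def compare(arm_screen: "ArmResult", arm_none: "ArmResult", wtp: float) -> ComparisonResult:
    """Incremental comparison of the screening arm against no screening."""
    dc = arm_screen.cost_pp - arm_none.cost_pp
    dq = arm_screen.qaly_pp - arm_none.qaly_pp
    nmb_s = nmb(arm_screen.cost_pp, arm_screen.qaly_pp, wtp)
    nmb_n = nmb(arm_none.cost_pp, arm_none.qaly_pp, wtp)
    icer, label = _classify(dc, dq)
    return ComparisonResult(
        cost_screen=arm_screen.cost_pp,
        cost_none=arm_none.cost_pp,
        qaly_screen=arm_screen.qaly_pp,
        qaly_none=arm_none.qaly_pp,
        wtp=wtp,
        delta_cost=dc,
        delta_qaly=dq,
        nmb_screen=nmb_s,
        nmb_none=nmb_n,
        inmb=dq * wtp - dc,
        icer=icer,
        dominance=label,
    )
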