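"""Quarterly Markov cohort engine with discounted cost and QALY ledgers.

Six health states: disease-free, mild, moderate (braced / unbraced),
severe (awaiting surgery), and post-operative stable.  There is no death
state and no incidence into the cohort; the disease-free and post-operative
rows of the transition matrix are identity.

Accounting conventions
----------------------
* Discounting at cycle start: cycle k carries factor (1+r)^(-k*cycle_years),
  cycle 0 undiscounted.
* Utilities and per-cycle follow-up costs accrue on the occupancy at the
  start of each of the ``horizon_cycles`` cycles.
* One-time costs (surgery, in-model brace initiation) are charged on the
  transition mass at the destination cycle's discount factor.
* Follow-up costs accrue only to diagnosed occupants of the mild, moderate
  and severe states; undiagnosed occupants progress but cost nothing until
  clinical presentation at the severe state (switchable).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import economics
from .cascade import (
    InitialState,
    no_screening_arm_initial_state,
    screening_arm_initial_state,
)
from .parameters import ModelParameters

__all__ = [
    "HealthState",
    "build_transition_matrix",
    "discount_factor",
    "CohortTrace",
    "ArmResult",
    "run_cohort",
    "run_arm",
    "run_comparison",
]


class HealthState(enum.IntEnum):
    NO_AIS = 0
    MILD = 1
    MODERATE_BRACED = 2
    MODERATE_UNBRACED = 3
    SEVERE = 4
    POST_OP = 5


STATE_LABELS = [
    "no_ais", "mild", "moderate_braced", "moderate_unbraced", "severe", "post_op",
]

#: states whose diagnosed occupants accrue per-cycle follow-up costs
_FOLLOWUP_STATES = np.array([False, True, True, True, True, False])


def utilities_vector(params: ModelParameters) -> np.ndarray:
    return np.array(
        [
            params.u_noais, params.u_mild, params.u_mod_brace,
            params.u_mod_nobrace, params.u_sev, params.u_post,
        ]
    )


def build_transition_matrix(params: ModelParameters, diagnosed: bool) -> np.ndarray:
    """Row-stochastic 6x6 quarterly transition matrix.

    Diagnosed mild cases progressing to moderate are braced with
    probability ``p_brace_init``; undiagnosed cases always land unbraced.
    Severe cases move to the post-operative state with the per-cycle
    surgery probability, which enforces a surgical wait of at least one
    cycle.  Residual mass stays in place, so rows sum to one by
    construction.
    """
    params = params.with_derived()
    p_mm = params.p_mild_to_mod_cycle
    p_msu = params.p_mod_to_sev_nobrace_cycle
    p_msb = params.p_mod_to_sev_brace_cycle
    p_surg = params.p_sev_to_surg_cycle
    for name, p in (
        ("p_mild_to_mod_cycle", p_mm),
        ("p_mod_to_sev_nobrace_cycle", p_msu),
        ("p_mod_to_sev_brace_cycle", p_msb),
        ("p_sev_to_surg_cycle", p_surg),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")

    P = np.eye(6)
    s = HealthState
    if diagnosed:
        P[s.MILD, s.MODERATE_BRACED] = p_mm * params.p_brace_init
        P[s.MILD, s.MODERATE_UNBRACED] = p_mm * (1.0 - params.p_brace_init)
    else:
        P[s.MILD, s.MODERATE_UNBRACED] = p_mm
    P[s.MILD, s.MILD] = 1.0 - p_mm
    P[s.MODERATE_BRACED, s.SEVERE] = p_msb
    P[s.MODERATE_BRACED, s.MODERATE_BRACED] = 1.0 - p_msb
    P[s.MODERATE_UNBRACED, s.SEVERE] = p_msu
    P[s.MODERATE_UNBRACED, s.MODERATE_UNBRACED] = 1.0 - p_msu
    if diagnosed or params.clinical_presentation_at_severe:
        # surgery requires a diagnosis; undiagnosed severe cases reach it
        # only via the clinical-presentation pathway
        P[s.SEVERE, s.POST_OP] = p_surg
        P[s.SEVERE, s.SEVERE] = 1.0 - p_surg
    return P


def discount_factor(cycle_index: int, r: float, cycle_years: float) -> float:
    """Start-of-cycle discount factor ``(1+r)**(-k * cycle_years)``."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be nonnegative")
    if r <= -1:
        raise ValueError("discount rate must exceed -1")
    return float((1.0 + r) ** (-cycle_index * cycle_years))


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted cost/QALY ledgers.

    ``occupancy`` has ``horizon_cycles + 1`` rows (entry plus one per cycle
    boundary); the cost and QALY arrays have one entry per cycle.
    ``event_costs`` separates the one-time surgery and brace charges from
    the recurring follow-up stream in ``cycle_costs``.
    """

    occupancy: np.ndarray
    occupancy_diagnosed: np.ndarray
    occupancy_undiagnosed: np.ndarray
    cycle_costs: np.ndarray
    cycle_qalys: np.ndarray
    event_costs: dict[str, np.ndarray]

    @property
    def total_cost(self) -> float:
        return float(
            self.cycle_costs.sum() + sum(v.sum() for v in self.event_costs.values())
        )

    @property
    def total_qaly(self) -> float:
        return float(self.cycle_qalys.sum())

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle boundary: occupancies plus discounted ledgers."""
        n_rows = self.occupancy.shape[0]
        data = {"cycle": np.arange(n_rows)}
        for j, label in enumerate(STATE_LABELS):
            data[label] = self.occupancy[:, j]
        cost = np.zeros(n_rows)
        qaly = np.zeros(n_rows)
        cost[: len(self.cycle_costs)] = self.cycle_costs + sum(
            self.event_costs.values()
        )
        qaly[: len(self.cycle_qalys)] = self.cycle_qalys
        data["discounted_cost"] = cost
        data["discounted_qaly"] = qaly
        return pd.DataFrame(data)


@dataclass
class ArmResult:
    """Discounted per-person economics of one strategy arm."""

    cost_pp: float
    qaly_pp: float
    upfront_cost_pp: float
    trace: CohortTrace

    def validate(self, params: ModelParameters) -> "ArmResult":
        if self.cost_pp < 0:
            raise ValueError("negative per-person cost")
        if self.qaly_pp > params.horizon_years + 1e-9:
            raise ValueError("per-person QALY exceeds the horizon")
        return self


def run_cohort(
    init: InitialState,
    params: ModelParameters,
    followup_cost_cycle: float,
) -> CohortTrace:
    """Propagate the cohort over the horizon, accruing discounted ledgers."""
    params = params.with_derived()
    init.validate()
    n_cycles = params.horizon_cycles
    P_d = build_transition_matrix(params, diagnosed=True)
    P_u = build_transition_matrix(params, diagnosed=False)
    util = utilities_vector(params)
    s = HealthState

    d = init.diagnosed.astype(float).copy()
    u = init.undiagnosed.astype(float).copy()

    occ_d = np.zeros((n_cycles + 1, 6))
    occ_u = np.zeros((n_cycles + 1, 6))
    cycle_costs = np.zeros(n_cycles)
    cycle_qalys = np.zeros(n_cycles)
    surgery_costs = np.zeros(n_cycles)
    brace_costs = np.zeros(n_cycles)

    disc = np.array(
        [discount_factor(k, params.r_discount, params.cycle_years) for k in range(n_cycles + 1)]
    )

    for k in range(n_cycles):
        if params.clinical_presentation_at_severe and u[s.SEVERE] > 0:
            d[s.SEVERE] += u[s.SEVERE]
            u[s.SEVERE] = 0.0
        occ_d[k], occ_u[k] = d, u

        cycle_qalys[k] = (d + u) @ util * params.cycle_years * disc[k]
        cycle_costs[k] = d[_FOLLOWUP_STATES].sum() * followup_cost_cycle * disc[k]

        surgery_mass = d[s.SEVERE] * P_d[s.SEVERE, s.POST_OP] + u[s.SEVERE] * P_u[
            s.SEVERE, s.POST_OP
        ]
        brace_mass = d[s.MILD] * P_d[s.MILD, s.MODERATE_BRACED]
        surgery_costs[k] = surgery_mass * params.c_surgery * disc[k + 1]
        brace_costs[k] = brace_mass * params.c_brace * disc[k + 1]

        d = d @ P_d
        u = u @ P_u

    if params.clinical_presentation_at_severe and u[s.SEVERE] > 0:
        d[s.SEVERE] += u[s.SEVERE]
        u[s.SEVERE] = 0.0
    occ_d[n_cycles], occ_u[n_cycles] = d, u

    return CohortTrace(
        occupancy=occ_d + occ_u,
        occupancy_diagnosed=occ_d,
        occupancy_undiagnosed=occ_u,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
        event_costs={"surgery": surgery_costs, "brace": brace_costs},
    )


def run_arm(params: ModelParameters, arm: str) -> ArmResult:
    """Compose the decision-tree entry conditions with the cohort engine."""
    params = params.with_derived().validate()
    if arm == "screening":
        init = screening_arm_initial_state(params)
        fu_cost = params.c_fu_screen_cycle
    elif arm == "no_screening":
        init = no_screening_arm_initial_state(params)
        fu_cost = params.c_fu_noscreen_cycle
    else:
        raise ValueError("arm must be 'screening' or 'no_screening'")
    trace = run_cohort(init, params, fu_cost)
    return ArmResult(
        cost_pp=init.upfront_cost_per_person + trace.total_cost,
        qaly_pp=trace.total_qaly,
        upfront_cost_pp=init.upfront_cost_per_person,
        trace=trace,
    ).validate(params)


def run_comparison(
    params: ModelParameters, wtp: float | None = None
) -> "economics.ComparisonResult":
    """Deterministic base-case comparison of the two strategies."""
    wtp = params.wtp if wtp is None else wtp
    screen = run_arm(params, "screening")
    none = run_arm(params, "no_screening")
    return economics.compare(screen, none, wtp)
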