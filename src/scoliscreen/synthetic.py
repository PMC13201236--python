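"""Synthetic individual-level data with the cascade's statistical structure.

Two generators:

* :func:`generate_cascade` draws individual screening-cascade records
  (Bernoulli suspicion, Bernoulli radiography completion, Bernoulli
  radiographic confirmation, multinomial severity, Bernoulli brace
  uptake) so every cascade statistic is testable without the program's
  raw records.
* :func:`microsimulate` walks individuals through the quarterly
  transition probabilities with the same utility, cost and discounting
  conventions as the cohort engine, serving as its stochastic oracle.

Each cohort uses a single seeded NumPy generator; all draws are
vectorized over individuals, so a fixed seed reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import CascadeCounts, InitialState, cascade_rates_from_counts, expected_counts
from .markov import (
    HealthState,
    build_transition_matrix,
    discount_factor,
    utilities_vector,
    _FOLLOWUP_STATES,
)
from .parameters import ModelParameters

__all__ = ["SyntheticCohort", "generate_cascade", "summarize_cascade", "microsimulate"]

SEVERITY_LABELS = np.array(["none", "mild", "moderate", "severe"])


@dataclass
class SyntheticCohort:
    """Individual-level records plus the generator's provenance.

    ``table`` holds one row per individual.  Cascade cohorts carry the
    columns ``id, suspected, completed_xray, confirmed, severity, braced``;
    microsimulated cohorts add ``start_state, final_state, diagnosed,
    cost, qaly`` and expose the full per-cycle state paths in
    ``state_paths`` (individuals x cycle boundaries).
    """

    table: pd.DataFrame
    seed: int
    generating_params: ModelParameters
    state_paths: np.ndarray | None = None


def generate_cascade(params: ModelParameters, n: int, seed: int) -> SyntheticCohort:
    """Draw ``n`` individual screening-cascade records.

    Suspicion, radiography completion, confirmation and brace uptake are
    Bernoulli at the parameter set's cascade rates; severity of confirmed
    cases is categorical at the confirmed-case proportions.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    rates = cascade_rates_from_counts(expected_counts(params))

    suspected = rng.random(n) < rates.suspected_rate
    completed = suspected & (rng.random(n) < rates.completion_rate)
    confirmed = completed & (rng.random(n) < min(rates.ppv_xray, 1.0))

    severity = np.zeros(n, dtype=np.int8)  # 0 = none
    idx = np.flatnonzero(confirmed)
    if idx.size:
        cum = np.cumsum(rates.severity_props)
        severity[idx] = 1 + (rng.random(idx.size)[:, None] > cum[None, :2]).sum(axis=1)
    braced = (severity == 2) & (rng.random(n) < params.p_brace_init)

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "suspected": suspected,
            "completed_xray": completed,
            "confirmed": confirmed,
            "severity": SEVERITY_LABELS[severity],
            "braced": braced,
        }
    )
    return SyntheticCohort(table=table, seed=seed, generating_params=params)


def summarize_cascade(cohort: SyntheticCohort) -> CascadeCounts:
    """Exact tallies of a synthetic cohort's cascade flags."""
    t = cohort.table
    return CascadeCounts(
        n_screened=float(len(t)),
        n_suspected=float(t["suspected"].sum()),
        n_xrayed=float(t["completed_xray"].sum()),
        n_mild=float((t["severity"] == "mild").sum()),
        n_moderate=float((t["severity"] == "moderate").sum()),
        n_severe=float((t["severity"] == "severe").sum()),
        n_braced=float(t["braced"].sum()),
    ).validate()


def microsimulate(
    params: ModelParameters,
    init: InitialState,
    n: int,
    seed: int,
    followup_cost_cycle: float | None = None,
) -> SyntheticCohort:
    """Individual-level walk through the quarterly transition model.

    Start states are drawn from the entry occupancy (diagnosed and
    undiagnosed strata separately); per-cycle transitions, utility
    accrual, follow-up costs, clinical presentation of undiagnosed severe
    cases, and one-time surgery/brace charges mirror the cohort engine,
    including start-of-cycle discounting.  The entry occupancy's up-front
    per-person cost is charged to every individual.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params.with_derived().validate()
    init.validate()
    if followup_cost_cycle is None:
        followup_cost_cycle = params.c_fu_screen_cycle
    rng = np.random.default_rng(seed)
    n_cycles = params.horizon_cycles
    s = HealthState

    p12 = np.concatenate([init.diagnosed, init.undiagnosed])
    p12 = np.maximum(p12, 0.0)
    p12 = p12 / p12.sum()
    start = rng.choice(12, size=n, p=p12)
    states = (start % 6).astype(np.int8)
    diagnosed = start < 6

    P_d = build_transition_matrix(params, diagnosed=True)
    P_u = build_transition_matrix(params, diagnosed=False)
    cum_d = np.cumsum(P_d, axis=1)
    cum_u = np.cumsum(P_u, axis=1)
    util = utilities_vector(params)
    disc = np.array(
        [discount_factor(k, params.r_discount, params.cycle_years) for k in range(n_cycles + 1)]
    )

    cost = np.full(n, init.upfront_cost_per_person)
    qaly = np.zeros(n)
    paths = np.empty((n, n_cycles + 1), dtype=np.int8)
    start_states = states.copy()

    for k in range(n_cycles):
        if params.clinical_presentation_at_severe:
            diagnosed |= states == s.SEVERE
        paths[:, k] = states

        qaly += util[states] * params.cycle_years * disc[k]
        cost[diagnosed & _FOLLOWUP_STATES[states]] += followup_cost_cycle * disc[k]

        rowcum = np.where(diagnosed[:, None], cum_d[states], cum_u[states])
        nxt = (rng.random(n)[:, None] > rowcum[:, :5]).sum(axis=1).astype(np.int8)

        cost[(states == s.SEVERE) & (nxt == s.POST_OP)] += params.c_surgery * disc[k + 1]
        cost[diagnosed & (states == s.MILD) & (nxt == s.MODERATE_BRACED)] += (
            params.c_brace * disc[k + 1]
        )
        states = nxt

    if params.clinical_presentation_at_severe:
        diagnosed |= states == s.SEVERE
    paths[:, n_cycles] = states

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "start_state": start_states,
            "final_state": states,
            "diagnosed": diagnosed,
            "cost": cost,
            "qaly": qaly,
        }
    )
    return SyntheticCohort(
        table=table, seed=seed, generating_params=params, state_paths=paths
    )
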