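"""Markov cohort engine: matrices, discounting, traces, arm economics."""

import dataclasses

import numpy as np
import pytest

from scoliscreen import (
    InitialState,
    build_transition_matrix,
    default_parameters,
    discount_factor,
    run_arm,
    run_cohort,
)
from scoliscreen.markov import HealthState as S


def closed_form_full_health_qaly(p):
    """Geometric sum of discounted cycle lengths at utility 1."""
    g = (1.0 + p.r_discount) ** (-p.cycle_years)
    return p.cycle_years * (1.0 - g**p.horizon_cycles) / (1.0 - g)


def test_transition_matrix_structure(params):
    for diagnosed in (True, False):
        P = build_transition_matrix(params, diagnosed)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert ((P >= 0) & (P <= 1)).all()
        assert np.allclose(P[S.NO_AIS], np.eye(6)[S.NO_AIS])  # no incidence
        assert np.allclose(P[S.POST_OP], np.eye(6)[S.POST_OP])  # absorbing
        assert P[S.SEVERE, S.POST_OP] == pytest.approx(0.4377, abs=5e-5)
    P_u = build_transition_matrix(params, diagnosed=False)
    assert P_u[S.MILD, S.MODERATE_BRACED] == 0.0  # no bracing without diagnosis


def test_zero_progression_gives_identity(params):
    p = dataclasses.replace(
        params,
        p_mild_to_mod_cycle=0.0,
        p_mod_to_sev_nobrace_cycle=0.0,
        p_mod_to_sev_brace_cycle=0.0,
        p_sev_to_surg_cycle=0.0,
    )
    assert np.allclose(build_transition_matrix(p, True), np.eye(6))


@pytest.mark.parametrize(
    "cycle, expected",
    [(0, 1.0), (4, 0.952381), (16, 0.822702)],
)
def test_discount_factors(cycle, expected):
    assert discount_factor(cycle, 0.05, 0.25) == pytest.approx(expected, abs=5e-7)


def test_discount_factor_errors():
    with pytest.raises(ValueError):
        discount_factor(-1, 0.05, 0.25)
    with pytest.raises(ValueError):
        discount_factor(1, -1.0, 0.25)


def _init_all(state: int, diagnosed: bool = True) -> InitialState:
    d, u = np.zeros(6), np.zeros(6)
    (d if diagnosed else u)[state] = 1.0
    return InitialState(d, u, 0.0)


def test_full_health_cohort_matches_geometric_sum(params):
    trace = run_cohort(_init_all(S.NO_AIS, diagnosed=False), params, 0.0)
    assert trace.total_qaly == pytest.approx(closed_form_full_health_qaly(params), abs=1e-9)
    assert trace.total_qaly == pytest.approx(3.656086, abs=1e-6)
    assert trace.total_cost == 0.0
    # identity dynamics: occupancy constant across all rows
    assert np.allclose(trace.occupancy, trace.occupancy[0], atol=1e-15)


def test_forced_surgery_transition(params):
    p = dataclasses.replace(params, p_sev_to_surg_cycle=1.0)
    trace = run_cohort(_init_all(S.SEVERE), p, 0.0)
    assert trace.occupancy[1:, S.POST_OP] == pytest.approx(1.0)
    # one surgery per person, charged at the cycle-1 discount factor
    expected = p.c_surgery * discount_factor(1, p.r_discount, p.cycle_years)
    assert trace.event_costs["surgery"].sum() == pytest.approx(expected, rel=1e-12)
    assert trace.event_costs["surgery"][0] == pytest.approx(expected, rel=1e-12)


def test_undiagnosed_severe_present_clinically(params):
    trace = run_cohort(_init_all(S.SEVERE, diagnosed=False), params, 0.0)
    # transferred to the diagnosed stratum at entry, then operated on
    assert trace.occupancy_undiagnosed.sum() == 0.0
    assert trace.event_costs["surgery"].sum() > 0.0

    off = dataclasses.replace(params, clinical_presentation_at_severe=False)
    trace_off = run_cohort(_init_all(S.SEVERE, diagnosed=False), off, 0.0)
    assert trace_off.event_costs["surgery"].sum() == 0.0


def test_probability_conservation_each_cycle(params):
    for arm in ("screening", "no_screening"):
        trace = run_arm(params, arm).trace
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        postop = trace.occupancy[:, S.POST_OP]
        assert (np.diff(postop) >= -1e-15).all()  # absorbing state non-decreasing


def test_degenerate_arm_costs_only_screening_organisation(params):
    p = dataclasses.replace(
        params, n_suspected=0.0, n_confirmed_by_severity=(0.0, 0.0, 0.0)
    )
    arm = run_arm(p, "screening")
    assert arm.cost_pp == pytest.approx(p.c_screen_total / p.n_screened, rel=1e-12)
    assert arm.qaly_pp == pytest.approx(closed_form_full_health_qaly(p), abs=1e-9)


def test_monotone_responses(params):
    base_s = run_arm(params, "screening")
    base_n = run_arm(params, "no_screening")

    richer_u = dataclasses.replace(params, u_mild=min(params.u_mild + 0.02, 1.0))
    assert run_arm(richer_u, "screening").qaly_pp >= base_s.qaly_pp

    pricier = dataclasses.replace(params, c_surgery=params.c_surgery * 2)
    assert run_arm(pricier, "screening").cost_pp >= base_s.cost_pp
    assert run_arm(pricier, "no_screening").cost_pp >= base_n.cost_pp

    # weaker bracing effect (HR toward 1) -> more surgery in the screening arm
    weaker = dataclasses.replace(params, hr_brace=1.0, p_mod_to_sev_brace_cycle=None)
    more_postop = run_arm(weaker, "screening").trace.occupancy[-1, S.POST_OP]
    assert more_postop >= base_s.trace.occupancy[-1, S.POST_OP]


def test_trace_export_layout(params):
    frame = run_arm(params, "screening").trace.to_frame()
    assert list(frame.columns[:2]) == ["cycle", "no_ais"]
    assert len(frame) == params.horizon_cycles + 1
    assert frame["discounted_cost"].iloc[-1] == 0.0  # accrual rows only
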