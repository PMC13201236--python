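"""Screening cascade: rates, prevalence imputation, arm entry conditions."""

import dataclasses
import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scoliscreen import (
    CascadeCounts,
    ParameterError,
    cascade_rates_from_counts,
    default_parameters,
    no_screening_arm_initial_state,
    parameters_from_counts,
    read_cascade_counts,
    screening_arm_initial_state,
    true_prevalence,
)
from scoliscreen.markov import HealthState as S


def test_program_rates(program_counts):
    r = cascade_rates_from_counts(program_counts)
    assert r.suspected_rate == pytest.approx(0.0230, abs=5e-5)
    assert r.completion_rate == pytest.approx(0.277, abs=5e-4)
    assert r.ppv_xray == pytest.approx(0.512, abs=5e-4)
    assert r.ppv_two_stage == pytest.approx(0.142, abs=5e-4)
    assert r.detection_rate == pytest.approx(0.00326, abs=1e-5)
    assert r.brace_rate == pytest.approx(0.902, abs=5e-4)
    assert sum(r.severity_props) == pytest.approx(1.0, abs=1e-12)


def test_rates_are_scale_invariant(program_counts):
    doubled = CascadeCounts(
        **{k: 2 * v for k, v in dataclasses.asdict(program_counts).items()}
    )
    r1, r2 = cascade_rates_from_counts(program_counts), cascade_rates_from_counts(doubled)
    assert r1 == r2


def test_zero_downstream_counts_yield_zero_rates():
    counts = CascadeCounts(1000, 0, 0, 0, 0, 0, 0)
    r = cascade_rates_from_counts(counts)
    assert (r.suspected_rate, r.completion_rate, r.ppv_xray, r.detection_rate) == (
        0, 0, 0, 0,
    )


def test_invalid_counts_rejected():
    with pytest.raises(ParameterError):
        CascadeCounts(100, 200, 0, 0, 0, 0, 0).validate()
    with pytest.raises(ParameterError):
        CascadeCounts(100, 50, 10, 20, 0, 0, 0).validate()


def test_true_prevalence_base_case(params):
    p_true, props = true_prevalence(params)
    # 172 confirmed + (1211 - 336.05) x 0.5118 ~ 447.8 imputed cases
    assert p_true == pytest.approx(0.011767, abs=2e-5)
    assert props == pytest.approx((118 / 172, 41 / 172, 13 / 172))


def test_true_prevalence_limits(params):
    full = dataclasses.replace(params, p_confirm_completion=1.0)
    p_true, _ = true_prevalence(full)
    assert p_true == pytest.approx(172 / 52678, rel=1e-9)  # no non-completers
    none = dataclasses.replace(params, n_confirmed_by_severity=(0.0, 0.0, 0.0))
    assert true_prevalence(none)[0] == 0.0


def test_screening_entry_occupancy_and_costs(params):
    init = screening_arm_initial_state(params)
    n = params.n_screened
    assert init.occupancy.sum() == pytest.approx(1.0, abs=1e-12)
    assert init.diagnosed[S.MILD] == pytest.approx(118 / n)
    assert init.diagnosed[S.MODERATE_BRACED] == pytest.approx(41 * 0.90244 / n)
    assert init.diagnosed[S.MODERATE_UNBRACED] == pytest.approx(41 * 0.09756 / n)
    assert init.diagnosed[S.SEVERE] == pytest.approx(13 / n)
    # organisational component alone is 0.1760 US$/person
    assert params.c_screen_total / n == pytest.approx(0.1760, abs=5e-5)
    assert init.upfront_cost_per_person > params.c_screen_total / n


def test_screening_entry_degenerate_no_disease(params):
    p = dataclasses.replace(
        params, n_suspected=0.0, n_confirmed_by_severity=(0.0, 0.0, 0.0)
    )
    init = screening_arm_initial_state(p)
    assert init.occupancy == pytest.approx(np.eye(6)[0])
    assert init.upfront_cost_per_person == pytest.approx(p.c_screen_total / p.n_screened)


def test_no_screening_entry(params):
    init = no_screening_arm_initial_state(params)
    assert init.occupancy.sum() == pytest.approx(1.0, abs=1e-12)
    diag_cases = init.diagnosed.sum()
    moderate = init.diagnosed[S.MODERATE_BRACED] + init.diagnosed[S.MODERATE_UNBRACED]
    assert moderate / diag_cases == pytest.approx(0.521, abs=1e-9)

    missed_all = dataclasses.replace(params, theta_miss=1.0)
    init1 = no_screening_arm_initial_state(missed_all)
    assert init1.diagnosed.sum() == 0.0
    assert init1.upfront_cost_per_person == 0.0


def test_disease_mass_conserved_across_arms(params):
    scr = screening_arm_initial_state(params)
    non = no_screening_arm_initial_state(params)
    disease = slice(1, 6)
    assert scr.occupancy[disease].sum() == pytest.approx(
        non.occupancy[disease].sum(), abs=1e-12
    )


@settings(derandomize=True, max_examples=60)
@given(
    completion=st.floats(min_value=0.05, max_value=1.0),
    theta=st.floats(min_value=0.0, max_value=1.0),
    brace=st.floats(min_value=0.0, max_value=1.0),
    counts=st.tuples(
        st.floats(min_value=0, max_value=200),
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=50),
    ),
)
def test_entry_occupancy_is_probability_vector(completion, theta, brace, counts):
    """Both arms' entry occupancies stay on the simplex for admissible params."""
    p = dataclasses.replace(
        default_parameters(),
        p_confirm_completion=completion,
        theta_miss=theta,
        p_brace_init=brace,
        n_confirmed_by_severity=counts,
    ).validate()
    for init in (screening_arm_initial_state(p), no_screening_arm_initial_state(p)):
        occ = init.occupancy
        assert (occ >= -1e-12).all()
        assert occ.sum() == pytest.approx(1.0, abs=1e-9)
        assert init.upfront_cost_per_person >= 0.0


def test_counts_round_trip_and_reader(program_counts):
    p = parameters_from_counts(program_counts)
    assert p.p_confirm_completion == pytest.approx(336 / 1211)
    assert p.p_brace_init == pytest.approx(37 / 41)
    text = (
        "n_screened,n_suspected,n_xrayed,n_mild,n_moderate,n_severe,n_braced\n"
        "52678,1211,336,118,41,13,37\n"
    )
    assert read_cascade_counts(io.StringIO(text)) == program_counts
    with pytest.raises(ParameterError, match="missing columns"):
        read_cascade_counts(io.StringIO("a,b\n1,2\n"))
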