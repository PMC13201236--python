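"""One-way and probabilistic sensitivity analyses, CEAC, scenarios."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from scoliscreen import (
    SCENARIOS,
    PsaSummary,
    ceac,
    default_parameters,
    owsa,
    run_comparison,
    run_psa,
    run_scenario,
    sample_parameters,
)


def _fixed_params(params):
    """Parameter set with every distribution spec removed (all fixed)."""
    return dataclasses.replace(params, specs={})


def test_owsa_all_fixed_is_empty(params):
    assert owsa(_fixed_params(params)) == []


def test_owsa_sorted_by_span_with_bounds_re_deriving(params):
    entries = owsa(params)
    spans = [e.span for e in entries]
    assert spans == sorted(spans, reverse=True)
    names = {e.parameter_name for e in entries}
    # derived probabilities are never perturbed independently
    assert "p_mod_to_sev_brace_cycle" not in names
    assert "p_sev_to_surg_cycle" not in names
    assert "hr_brace" in names and "p_surgery_annual" in names
    assert all(e.span >= 0 for e in entries)


def test_cost_parameters_leave_delta_qaly_unchanged(params):
    base = run_comparison(params)
    pricier = run_comparison(dataclasses.replace(params, c_surgery=3000.0))
    assert pricier.delta_qaly == pytest.approx(base.delta_qaly, abs=1e-15)


def test_sample_parameters_determinism_and_fixed_identity(params):
    fixed = _fixed_params(params)
    rng = np.random.default_rng(5)
    assert sample_parameters(fixed, rng) == fixed  # all point masses

    rng_a, rng_b = np.random.default_rng(7), np.random.default_rng(7)
    d1 = [sample_parameters(params, rng_a) for _ in range(3)]
    d2 = [sample_parameters(params, rng_b) for _ in range(3)]
    assert d1 == d2
    assert d1[0] != d1[1]  # stream advances


def test_sampled_derived_quantities_recomputed(params):
    draw = sample_parameters(params, np.random.default_rng(11))
    from scoliscreen import apply_hazard_ratio, convert_prob_timescale

    assert draw.p_mod_to_sev_brace_cycle == pytest.approx(
        apply_hazard_ratio(draw.p_mod_to_sev_nobrace_cycle, draw.hr_brace), abs=1e-12
    )
    assert draw.p_sev_to_surg_cycle == pytest.approx(
        convert_prob_timescale(draw.p_surgery_annual, 1.0, 0.25), abs=1e-12
    )


def test_sample_mean_matches_moment_target(params):
    rng = np.random.default_rng(2024)
    draws = np.array(
        [sample_parameters(params, rng).p_confirm_completion for _ in range(3000)]
    )
    se = 0.02832 / np.sqrt(len(draws))
    assert abs(draws.mean() - 0.2775) < 3 * se


def test_psa_reproducible_and_quadrants_sum_to_one(params):
    s1 = run_psa(params, n_iter=40, seed=123)
    s2 = run_psa(params, n_iter=40, seed=123)
    pd.testing.assert_frame_equal(s1.draws, s2.draws)
    assert s1.ceac == s2.ceac
    assert sum(s1.quadrant_props.values()) == pytest.approx(1.0, abs=1e-9)


def test_psa_single_fixed_draw_equals_base_case(params):
    fixed = _fixed_params(params)
    summary = run_psa(fixed, n_iter=1, seed=9)
    base = run_comparison(fixed)
    row = summary.draws.iloc[0]
    assert row["delta_cost"] == pytest.approx(base.delta_cost, abs=1e-12)
    assert row["delta_qaly"] == pytest.approx(base.delta_qaly, abs=1e-12)


def _single_draw_summary(dc, dq, wtp=1000.0):
    draws = pd.DataFrame(
        {"iter": [0], "delta_cost": [dc], "delta_qaly": [dq], "inmb": [dq * wtp - dc]}
    )
    return PsaSummary(draws=draws, n_iter=1, seed=0, wtp=wtp)


def test_ceac_threshold_behaviour():
    always = ceac(_single_draw_summary(-1.0, 0.0), wtp_grid=[0, 500, 5000])
    assert [p for _, p in always] == [1.0, 1.0, 1.0]

    stepped = ceac(_single_draw_summary(1.0, 0.001), wtp_grid=[0, 999, 1001, 5000])
    assert [p for _, p in stepped] == [0.0, 0.0, 1.0, 1.0]

    with pytest.raises(ValueError):
        ceac(_single_draw_summary(1.0, 0.001), wtp_grid=[])


def test_ceac_probabilities_are_draw_fractions(params):
    summary = run_psa(params, n_iter=8, seed=3)
    for _, p in summary.ceac:
        assert p in {i / 8 for i in range(9)}
    # curve is recomputable from the same draw set (no resampling)
    assert ceac(summary) == summary.ceac


def test_scenario_empty_overrides_identical_to_base(params):
    base = run_comparison(params)
    scen = run_scenario(params, {})
    assert scen.inmb == pytest.approx(base.inmb, abs=1e-12)
    assert scen.delta_cost == pytest.approx(base.delta_cost, abs=1e-12)


def test_scenario_horizon_override_full_health_qaly(params):
    p = dataclasses.replace(
        params, n_suspected=0.0, n_confirmed_by_severity=(0.0, 0.0, 0.0)
    )
    scen = run_scenario(p, {"horizon_cycles": 8})
    g = 1.05 ** (-0.25)
    closed_form = 0.25 * (1 - g**8) / (1 - g)
    assert scen.qaly_screen == pytest.approx(closed_form, abs=1e-9)


def test_named_scenarios_run_and_differ(params):
    a = run_scenario(params, SCENARIOS["A"])
    b = run_scenario(params, SCENARIOS["B"])
    assert a.inmb != b.inmb
    assert a.dominance == "dominant" and b.dominance == "dominant"


def test_scenario_rejects_unknown_override(params):
    from scoliscreen import ParameterError

    with pytest.raises(ParameterError, match="bogus"):
        run_scenario(params, {"bogus": 1.0})
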