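"""Sensitivity analyses: tornado (one-way), probabilistic, CEAC, scenarios.

The one-way analysis perturbs each uncertain parameter to its resolved
low and high bound with everything else at base, re-derives the dependent
per-cycle probabilities from the perturbed primitive, and records the
incremental net monetary benefit at each bound.  The probabilistic
analysis jointly samples all uncertain parameters from their
moment-matched distributions (severity mixes as single Dirichlet draws)
and evaluates the full model per draw; the acceptability curve is
computed from the same draw set as the cost-utility plane.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import ComparisonResult
from .markov import run_comparison
from .parameters import (
    DEFAULT_SEED,
    ModelParameters,
    ParameterError,
    moment_match,
    resolve_bounds,
)

__all__ = [
    "TornadoEntry",
    "PsaSummary",
    "owsa",
    "sample_parameters",
    "run_psa",
    "ceac",
    "run_scenario",
    "SCENARIOS",
]

logger = logging.getLogger(__name__)

#: Named scenarios for the no-screening arm: A models strong routine
#: diagnostic capacity (few missed cases, late-presentation mix shifted
#: severe), B weak capacity.
SCENARIOS: dict[str, dict[str, object]] = {
    "A": {"theta_miss": 0.15, "pi_init_noscreen": (0.15, 0.50, 0.35)},
    "B": {"theta_miss": 0.50, "pi_init_noscreen": (0.35, 0.50, 0.15)},
}

# derived per-cycle probabilities and the primitives they depend on
_DERIVED_RESET = {
    "p_mod_to_sev_nobrace_cycle": ("p_mod_to_sev_brace_cycle",),
    "hr_brace": ("p_mod_to_sev_brace_cycle",),
    "p_surgery_annual": ("p_sev_to_surg_cycle",),
}

_UNIT_FIELDS = {
    "p_confirm_completion", "p_brace_init", "p_mild_to_mod_cycle",
    "p_mod_to_sev_nobrace_cycle", "p_surgery_annual", "theta_miss",
    "u_mild", "u_mod_nobrace", "u_mod_brace", "u_sev", "u_post",
}


@dataclass(frozen=True)
class TornadoEntry:
    """INMB at the low and high bound of one parameter."""

    parameter_name: str
    inmb_low: float
    inmb_high: float

    @property
    def span(self) -> float:
        return abs(self.inmb_high - self.inmb_low)


def with_override(params: ModelParameters, name: str, value: object) -> ModelParameters:
    """Set one primitive and re-derive the quantities that depend on it."""
    changes: dict[str, object] = {name: value}
    for derived in _DERIVED_RESET.get(name, ()):
        changes[derived] = None
    return dataclasses.replace(params, **changes).with_derived()


def _clip_unit(name: str, value: float) -> float:
    if name in _UNIT_FIELDS and not 0.0 <= value <= 1.0:
        clipped = min(max(value, 0.0), 1.0)
        logger.info("OWSA bound for %s clipped from %g to %g", name, value, clipped)
        return clipped
    return value


def owsa(params: ModelParameters, wtp: float | None = None) -> list[TornadoEntry]:
    """One-way sensitivity analysis over every non-fixed scalar parameter.

    Entries come back sorted by descending INMB span, ties broken
    alphabetically by parameter name.  Dirichlet-distributed severity
    mixes have no scalar bounds and are excluded (they are exercised in
    the probabilistic analysis and the named scenarios).
    """
    params = params.with_derived().validate()
    wtp = params.wtp if wtp is None else wtp
    entries: list[TornadoEntry] = []
    for name, spec in params.specs.items():
        if spec.kind in {"fixed", "dirichlet"}:
            continue
        low, high = resolve_bounds(spec)
        if high == low:
            continue
        inmbs = []
        for bound in (low, high):
            bound = _clip_unit(name, bound)
            perturbed = with_override(params, name, bound).validate()
            inmbs.append(run_comparison(perturbed, wtp).inmb)
        entries.append(TornadoEntry(name, inmb_low=inmbs[0], inmb_high=inmbs[1]))
    return sorted(entries, key=lambda e: (-e.span, e.parameter_name))


_MAX_REDRAWS = 100


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator
) -> ModelParameters:
    """One joint draw of all uncertain parameters.

    Each scalar parameter is drawn independently from its moment-matched
    distribution; each severity triple is one Dirichlet draw.  Draws
    violating hard bounds (probabilities and utilities outside the unit
    interval) are redrawn up to a capped retry count.  Derived per-cycle
    probabilities are recomputed from the drawn primitives.
    """
    changes: dict[str, object] = {}
    for name, spec in params.specs.items():
        if spec.kind == "fixed":
            continue
        sampler = moment_match(spec, dirichlet_ess=params.dirichlet_ess)
        value = sampler.sample(rng)
        if isinstance(value, tuple):
            if name == "n_confirmed_by_severity":
                total = params.n_confirmed_total
                value = tuple(v * total for v in value)
            changes[name] = value
            continue
        tries = 0
        while name in _UNIT_FIELDS and not 0.0 <= value <= 1.0:
            tries += 1
            if tries > _MAX_REDRAWS:
                raise ParameterError(f"redraw cap exceeded for {name}")
            value = sampler.sample(rng)
        changes[name] = value
    for name in list(changes):
        for derived in _DERIVED_RESET.get(name, ()):
            changes[derived] = None
    return dataclasses.replace(params, **changes).with_derived().validate()


@dataclass
class PsaSummary:
    """Monte-Carlo draws on the cost-utility plane plus the CEAC."""

    draws: pd.DataFrame  # columns: iter, delta_cost, delta_qaly, inmb
    n_iter: int
    seed: int
    wtp: float
    quadrant_props: dict[str, float] = field(default_factory=dict)
    ceac: list[tuple[float, float]] = field(default_factory=list)

    @property
    def prob_cost_saving(self) -> float:
        return float((self.draws["delta_cost"] < 0).mean())

    @property
    def prob_cost_effective(self) -> float:
        return float((self.draws["inmb"] > 0).mean())


def _quadrants(dc: np.ndarray, dq: np.ndarray) -> dict[str, float]:
    n = len(dc)
    return {
        "cost_saving_more_effective": float(((dc < 0) & (dq >= 0)).sum() / n),
        "cost_saving_less_effective": float(((dc < 0) & (dq < 0)).sum() / n),
        "costlier_more_effective": float(((dc >= 0) & (dq >= 0)).sum() / n),
        "costlier_less_effective": float(((dc >= 0) & (dq < 0)).sum() / n),
    }


def run_psa(
    params: ModelParameters,
    n_iter: int = 3000,
    seed: int = DEFAULT_SEED,
    wtp: float | None = None,
) -> PsaSummary:
    """Probabilistic sensitivity analysis: ``n_iter`` full model runs."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    params = params.with_derived().validate()
    wtp = params.wtp if wtp is None else wtp
    rng = np.random.default_rng(seed)
    rows = np.empty((n_iter, 3))
    for i in range(n_iter):
        draw = sample_parameters(params, rng)
        cmp = run_comparison(draw, wtp)
        rows[i] = (cmp.delta_cost, cmp.delta_qaly, cmp.inmb)
    draws = pd.DataFrame(rows, columns=["delta_cost", "delta_qaly", "inmb"])
    draws.insert(0, "iter", np.arange(n_iter))
    summary = PsaSummary(
        draws=draws,
        n_iter=n_iter,
        seed=seed,
        wtp=wtp,
        quadrant_props=_quadrants(rows[:, 0], rows[:, 1]),
    )
    summary.ceac = ceac(summary)
    return summary


def ceac(
    summary: PsaSummary, wtp_grid: np.ndarray | list[float] | None = None
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve from the PSA draw set.

    At each threshold the probability is the fraction of draws with
    positive net benefit; the default grid spans 0 to three times the
    base willingness-to-pay (1x regional GDP per capita) in 100 steps.
    """
    if summary.draws.empty:
        raise ValueError("PSA draw set is empty")
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 3.0 * summary.wtp, 100)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp grid is empty")
    dq = summary.draws["delta_qaly"].to_numpy()
    dc = summary.draws["delta_cost"].to_numpy()
    nb = dq[None, :] * wtp_grid[:, None] - dc[None, :]
    probs = (nb > 0).mean(axis=1)
    return [(float(w), float(p)) for w, p in zip(wtp_grid, probs)]


def run_scenario(
    params: ModelParameters,
    overrides: dict[str, object] | None = None,
    wtp: float | None = None,
) -> ComparisonResult:
    """Deterministic run under named-parameter overrides.

    Empty overrides reproduce the base case.  Bundled scenarios live in
    :data:`SCENARIOS`; horizon and willingness-to-pay variants are plain
    overrides of ``horizon_cycles`` / ``wtp``.
    """
    scenario = dict(overrides or {})
    wtp_override = scenario.pop("wtp", None)
    if wtp_override is not None and wtp is None:
        wtp = float(wtp_override)  # type: ignore[arg-type]
    current = params
    for name, value in scenario.items():
        if not hasattr(current, name):
            raise ParameterError(f"unknown override {name!r}")
        if isinstance(value, (list, tuple)):
            value = tuple(float(v) for v in value)
        current = with_override(current, name, value)
    return run_comparison(current.validate(), wtp)
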