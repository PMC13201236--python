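"""Decision-tree stage: the screening cascade and arm entry conditions.

Turns screening-cascade counts (screened -> suspected -> radiographed ->
confirmed by severity -> braced) into summary rates, an estimate of true
disease prevalence among the screened cohort, and each strategy arm's
initial Markov state distribution together with its up-front per-person
cost.

Diagnosed and undiagnosed occupants of the same health state are tracked
separately: undiagnosed individuals progress identically but accrue no
diagnosis-dependent costs (no follow-up, no bracing) until — if the
clinical-presentation switch is on — they reach the severe state and
present clinically.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParameters, ParameterError

__all__ = [
    "CascadeCounts",
    "CascadeRates",
    "InitialState",
    "cascade_rates_from_counts",
    "expected_counts",
    "true_prevalence",
    "screening_arm_initial_state",
    "no_screening_arm_initial_state",
    "parameters_from_counts",
    "read_cascade_counts",
]

logger = logging.getLogger(__name__)

# state indices shared with the Markov engine
_NOAIS, _MILD, _MODB, _MODU, _SEV, _POST = range(6)

_COUNT_COLUMNS = [
    "n_screened", "n_suspected", "n_xrayed",
    "n_mild", "n_moderate", "n_severe", "n_braced",
]


@dataclass(frozen=True)
class CascadeCounts:
    """Counts observed along the screening cascade."""

    n_screened: float
    n_suspected: float
    n_xrayed: float
    n_mild: float
    n_moderate: float
    n_severe: float
    n_braced: float

    @property
    def n_confirmed_total(self) -> float:
        return self.n_mild + self.n_moderate + self.n_severe

    def validate(self) -> "CascadeCounts":
        if min(
            self.n_screened, self.n_suspected, self.n_xrayed,
            self.n_mild, self.n_moderate, self.n_severe, self.n_braced,
        ) < 0:
            raise ParameterError("cascade counts must be nonnegative")
        if self.n_suspected > self.n_screened:
            raise ParameterError("n_suspected exceeds n_screened")
        if self.n_xrayed > self.n_suspected:
            raise ParameterError("n_xrayed exceeds n_suspected")
        if self.n_confirmed_total > self.n_xrayed:
            raise ParameterError("confirmed total exceeds n_xrayed")
        if self.n_braced > self.n_moderate:
            raise ParameterError("n_braced exceeds n_moderate")
        return self


@dataclass(frozen=True)
class CascadeRates:
    """Summary rates of the cascade (all conditional probabilities)."""

    suspected_rate: float
    completion_rate: float
    ppv_xray: float
    ppv_two_stage: float
    detection_rate: float
    severity_props: tuple[float, float, float]
    brace_rate: float


@dataclass(frozen=True)
class InitialState:
    """Entry conditions of one strategy arm.

    ``diagnosed`` and ``undiagnosed`` are per-person occupancy vectors over
    the six health states; their sum is a probability vector.  The up-front
    cost bundles everything charged at model entry (screening organisation,
    confirmatory radiographs, initial braces), averaged over the whole
    screened cohort.
    """

    diagnosed: np.ndarray
    undiagnosed: np.ndarray
    upfront_cost_per_person: float

    @property
    def occupancy(self) -> np.ndarray:
        return self.diagnosed + self.undiagnosed

    def validate(self) -> "InitialState":
        occ = self.occupancy
        if (self.diagnosed < -1e-12).any() or (self.undiagnosed < -1e-12).any():
            raise ParameterError("negative occupancy at entry")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ParameterError(f"entry occupancy sums to {occ.sum()}, not 1")
        if self.upfront_cost_per_person < 0:
            raise ParameterError("upfront cost must be nonnegative")
        return self


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.info("cascade rate %s: zero denominator, returning 0", what)
        return 0.0
    return num / den


def cascade_rates_from_counts(counts: CascadeCounts) -> CascadeRates:
    """Summary rates from cascade counts; zero denominators yield 0."""
    counts.validate()
    if counts.n_screened <= 0:
        raise ParameterError("n_screened must be positive")
    confirmed = counts.n_confirmed_total
    props = (
        (counts.n_mild / confirmed, counts.n_moderate / confirmed, counts.n_severe / confirmed)
        if confirmed > 0
        else (0.0, 0.0, 0.0)
    )
    return CascadeRates(
        suspected_rate=_ratio(counts.n_suspected, counts.n_screened, "suspected_rate"),
        completion_rate=_ratio(counts.n_xrayed, counts.n_suspected, "completion_rate"),
        ppv_xray=_ratio(confirmed, counts.n_xrayed, "ppv_xray"),
        ppv_two_stage=_ratio(confirmed, counts.n_suspected, "ppv_two_stage"),
        detection_rate=_ratio(confirmed, counts.n_screened, "detection_rate"),
        severity_props=props,
        brace_rate=_ratio(counts.n_braced, counts.n_moderate, "brace_rate"),
    )


def expected_counts(params: ModelParameters) -> CascadeCounts:
    """Expected (continuous) cascade counts implied by the parameters."""
    mild, mod, sev = params.n_confirmed_by_severity
    return CascadeCounts(
        n_screened=params.n_screened,
        n_suspected=params.n_suspected,
        n_xrayed=params.n_suspected * params.p_confirm_completion,
        n_mild=mild,
        n_moderate=mod,
        n_severe=sev,
        n_braced=mod * params.p_brace_init,
    )


def true_prevalence(params: ModelParameters) -> tuple[float, tuple[float, float, float]]:
    """Estimated true AIS prevalence among the screened cohort.

    Suspected individuals who never completed radiography are assumed
    diseased at the radiographic positive-predictive rate, so the true
    case count is ``confirmed + (suspected - radiographed) * ppv_xray``.
    The severity mix of these undetected cases follows the confirmed-case
    severity proportions.
    """
    confirmed = params.n_confirmed_total
    n_xrayed = params.n_suspected * params.p_confirm_completion
    ppv = min(_ratio(confirmed, n_xrayed, "ppv_xray"), 1.0)
    undetected = (params.n_suspected - n_xrayed) * ppv
    p_true = (confirmed + undetected) / params.n_screened
    return p_true, params.severity_props


def screening_arm_initial_state(params: ModelParameters) -> InitialState:
    """Entry conditions under organized school-based screening.

    Confirmed cases enter their diagnosed severity states (moderate cases
    split by the brace-initiation probability); undetected true cases
    occupy disease states undiagnosed; everyone else starts disease-free.
    Up-front costs cover the screening organisation, one radiograph per
    completed confirmation, and one brace per initial brace initiation.
    """
    n = params.n_screened
    mild, mod, sev = params.n_confirmed_by_severity
    n_xrayed = params.n_suspected * params.p_confirm_completion
    n_braced = mod * params.p_brace_init

    diagnosed = np.zeros(6)
    diagnosed[_MILD] = mild / n
    diagnosed[_MODB] = n_braced / n
    diagnosed[_MODU] = mod * (1.0 - params.p_brace_init) / n
    diagnosed[_SEV] = sev / n

    p_true, props = true_prevalence(params)
    undetected_mass = max(p_true - params.n_confirmed_total / n, 0.0)
    undiagnosed = np.zeros(6)
    undiagnosed[_MILD] = undetected_mass * props[0]
    undiagnosed[_MODU] = undetected_mass * props[1]
    undiagnosed[_SEV] = undetected_mass * props[2]
    undiagnosed[_NOAIS] = 1.0 - diagnosed.sum() - undetected_mass

    upfront = (
        params.c_screen_total + n_xrayed * params.c_xray + n_braced * params.c_brace
    ) / n
    return InitialState(diagnosed, undiagnosed, upfront).validate()


def no_screening_arm_initial_state(params: ModelParameters) -> InitialState:
    """Entry conditions under opportunistic detection only.

    The same true-disease mass as in the screening arm enters the model; a
    fraction ``theta_miss`` is never diagnosed (severity mix equal to the
    confirmed-case proportions), while the remainder is diagnosed
    opportunistically at entry with the first-presentation severity mix
    ``pi_init_noscreen``, moderate cases braced at the brace-initiation
    rate.  Each diagnosed case is charged one confirmatory radiograph, and
    each initiated brace its one-time cost; there is no screening
    organisation cost.
    """
    p_true, props = true_prevalence(params)
    diag_mass = (1.0 - params.theta_miss) * p_true
    miss_mass = params.theta_miss * p_true
    pi = params.pi_init_noscreen

    diagnosed = np.zeros(6)
    diagnosed[_MILD] = diag_mass * pi[0]
    diagnosed[_MODB] = diag_mass * pi[1] * params.p_brace_init
    diagnosed[_MODU] = diag_mass * pi[1] * (1.0 - params.p_brace_init)
    diagnosed[_SEV] = diag_mass * pi[2]

    undiagnosed = np.zeros(6)
    undiagnosed[_MILD] = miss_mass * props[0]
    undiagnosed[_MODU] = miss_mass * props[1]
    undiagnosed[_SEV] = miss_mass * props[2]
    undiagnosed[_NOAIS] = 1.0 - p_true

    upfront = diag_mass * params.c_xray + diagnosed[_MODB] * params.c_brace
    return InitialState(diagnosed, undiagnosed, upfront).validate()


def parameters_from_counts(
    counts: CascadeCounts, base: ModelParameters | None = None
) -> ModelParameters:
    """Build a parameter set whose cascade block reflects observed counts."""
    import dataclasses

    from .parameters import default_parameters

    counts.validate()
    base = base if base is not None else default_parameters()
    rates = cascade_rates_from_counts(counts)
    return dataclasses.replace(
        base,
        n_screened=counts.n_screened,
        n_suspected=counts.n_suspected,
        p_confirm_completion=rates.completion_rate,
        n_confirmed_by_severity=(counts.n_mild, counts.n_moderate, counts.n_severe),
        p_brace_init=rates.brace_rate if counts.n_moderate > 0 else base.p_brace_init,
    ).validate()


def read_cascade_counts(source: str | io.TextIOBase) -> CascadeCounts:
    """Read cascade counts from delimited text with the canonical header.

    Expected columns, exactly: ``n_screened, n_suspected, n_xrayed, n_mild,
    n_moderate, n_severe, n_braced`` (one data row).
    """
    df = pd.read_csv(source)
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"cascade counts file missing columns: {missing}")
    if len(df) != 1:
        raise ParameterError("cascade counts file must contain exactly one row")
    row = df.iloc[0]
    return CascadeCounts(**{c: float(row[c]) for c in _COUNT_COLUMNS}).validate()
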