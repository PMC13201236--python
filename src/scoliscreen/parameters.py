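"""Model parameters for the scoliosis-screening cost-utility model.

Every symbol of the model lives here: screening-cascade counts and rates,
quarterly natural-history transition probabilities, the bracing hazard
ratio, health-state utilities, unit costs, discounting conventions, the
willingness-to-pay threshold, and the parameters describing opportunistic
detection in the no-screening arm (the missed-diagnosis proportion
``theta_miss`` and the severity mix at first presentation).

Each uncertain parameter carries a :class:`DistributionSpec` describing its
uncertainty range and distribution family (beta / gamma / lognormal /
dirichlet), which the sensitivity-analysis machinery moment-matches into
samplers.  All monetary amounts are stored internally in US dollars;
renminbi reporting is a presentation-layer conversion at ``fx_rate``.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "CurrencyConvention",
    "ModelParameters",
    "default_parameters",
    "literature_parameters",
    "load_parameters",
    "convert_currency",
    "resolve_bounds",
    "moment_match",
    "DEFAULT_SEED",
]

#: Default RNG seed recorded in output manifests; any seed is accepted.
DEFAULT_SEED = 20250512

_KINDS = {"fixed", "beta", "gamma", "lognormal", "dirichlet"}


class ParameterError(ValueError):
    """A model parameter violates its admissible range or failed to parse."""


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty specification for a single model parameter.

    Parameters
    ----------
    kind : {"fixed", "beta", "gamma", "lognormal", "dirichlet"}
        Distribution family used in probabilistic sensitivity analysis.
    base : float or tuple of float
        Base-case value (a probability simplex for ``dirichlet``).
    low, high : float, optional
        Explicit uncertainty bounds.  Mutually exclusive with
        ``relative_range``.
    relative_range : float, optional
        Symmetric relative half-width, e.g. ``0.20`` for "plus or minus 20
        percent" around the base value.
    ess : float, optional
        Effective sample size for ``dirichlet`` concentration
        (``alpha = base * ess``).
    """

    kind: str
    base: float | tuple[float, ...]
    low: float | None = None
    high: float | None = None
    relative_range: float | None = None
    ess: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "dirichlet":
            base = np.asarray(self.base, dtype=float)
            if base.ndim != 1 or abs(base.sum() - 1.0) > 1e-9:
                raise ParameterError(
                    "dirichlet base must be a probability vector summing to 1"
                )


def resolve_bounds(spec: DistributionSpec) -> tuple[float, float]:
    """Resolve a spec's uncertainty bounds to an explicit ``(low, high)``.

    A ``relative_range`` of *r* maps base *b* to ``(b*(1-r), b*(1+r))``;
    explicit bounds pass through.  Bounds of beta-distributed quantities
    (probabilities and utilities) are clipped to the unit interval.
    """
    if spec.kind == "dirichlet":
        raise ParameterError("dirichlet specs have no scalar bounds")
    b = float(spec.base)  # type: ignore[arg-type]
    if spec.low is not None and spec.high is not None:
        low, high = float(spec.low), float(spec.high)
    elif spec.relative_range is not None:
        r = spec.relative_range
        low, high = b * (1.0 - r), b * (1.0 + r)
    elif spec.kind == "fixed":
        return b, b
    else:
        raise ParameterError(
            "non-fixed spec needs explicit bounds or a relative_range"
        )
    if spec.kind == "beta":
        low, high = max(low, 0.0), min(high, 1.0)
    if not low <= b <= high:
        raise ParameterError(
            f"resolved bounds ({low}, {high}) do not bracket base {b}"
        )
    return low, high


# ---------------------------------------------------------------------------
# moment-matched samplers


class _Sampler:
    mean: float

    def sample(self, rng: np.random.Generator):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class PointMass(_Sampler):
    value: float | tuple[float, ...]

    @property
    def mean(self):
        return self.value

    def sample(self, rng):
        return self.value


@dataclass
class BetaSampler(_Sampler):
    a: float
    b: float

    @property
    def mean(self):
        return self.a / (self.a + self.b)

    def sample(self, rng):
        return float(rng.beta(self.a, self.b))


@dataclass
class GammaSampler(_Sampler):
    shape: float
    scale: float

    @property
    def mean(self):
        return self.shape * self.scale

    def sample(self, rng):
        return float(rng.gamma(self.shape, self.scale))


@dataclass
class LognormalSampler(_Sampler):
    mu: float
    sigma: float

    @property
    def median(self):
        return math.exp(self.mu)

    @property
    def mean(self):
        return math.exp(self.mu + 0.5 * self.sigma**2)

    def sample(self, rng):
        return float(rng.lognormal(self.mu, self.sigma))


@dataclass
class DirichletSampler(_Sampler):
    alpha: tuple[float, ...]

    @property
    def mean(self):
        a = np.asarray(self.alpha)
        return tuple(a / a.sum())

    def sample(self, rng):
        return tuple(float(x) for x in rng.dirichlet(self.alpha))


def moment_match(spec: DistributionSpec, dirichlet_ess: float = 172.0) -> _Sampler:
    """Turn a distribution spec into a moment-matched sampler.

    Beta and gamma are matched to ``mean = base`` and
    ``sd = (high - low) / (2 * 1.96)`` (the resolved range is read as a 95%
    interval).  Lognormal is matched to ``median = base`` with the bounds a
    95% interval on the ratio scale.  Dirichlet concentration is
    ``base * ess`` (``ess`` defaulting to the confirmed-case count).
    Degenerate spreads, or infeasible beta moments, collapse to a point
    mass (the latter with a warning).
    """
    if spec.kind == "dirichlet":
        ess = spec.ess if spec.ess is not None else dirichlet_ess
        alpha = tuple(float(p) * ess for p in spec.base)  # type: ignore[union-attr]
        return DirichletSampler(alpha)
    if spec.kind == "fixed":
        return PointMass(spec.base)

    low, high = resolve_bounds(spec)
    b = float(spec.base)  # type: ignore[arg-type]
    if high - low <= 0:
        return PointMass(b)

    if spec.kind == "lognormal":
        if low <= 0:
            raise ParameterError("lognormal bounds must be positive")
        return LognormalSampler(mu=math.log(b), sigma=(math.log(high) - math.log(low)) / (2 * 1.96))

    sd = (high - low) / (2 * 1.96)
    if spec.kind == "beta":
        var = sd * sd
        if b <= 0.0 or b >= 1.0 or var >= b * (1.0 - b):
            warnings.warn(
                f"infeasible beta moments (mean={b}, sd={sd:.4g}); using point mass",
                RuntimeWarning,
                stacklevel=2,
            )
            return PointMass(b)
        nu = b * (1.0 - b) / var - 1.0
        return BetaSampler(a=b * nu, b=(1.0 - b) * nu)
    if spec.kind == "gamma":
        if b <= 0:
            return PointMass(b)
        return GammaSampler(shape=(b / sd) ** 2, scale=sd * sd / b)
    raise ParameterError(f"unsupported kind {spec.kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# currency


@dataclass(frozen=True)
class CurrencyConvention:
    """Reporting currency and the CNY->USD conversion factor."""

    reporting_currency: str = "USD"
    fx_rate: float = 0.1404  # US$ per CNY

    def __post_init__(self) -> None:
        if self.fx_rate <= 0:
            raise ParameterError("fx_rate must be positive")
        if self.reporting_currency not in {"CNY", "USD"}:
            raise ParameterError("reporting_currency must be CNY or USD")


def convert_currency(
    amount: float, convention: CurrencyConvention, direction: str
) -> float:
    """Convert between CNY and USD; no rounding is applied internally."""
    if not math.isfinite(amount):
        raise ParameterError("amount must be finite")
    if direction == "CNY_TO_USD":
        return amount * convention.fx_rate
    if direction == "USD_TO_CNY":
        return amount / convention.fx_rate
    raise ParameterError("direction must be 'CNY_TO_USD' or 'USD_TO_CNY'")


# ---------------------------------------------------------------------------
# the parameter set


def _base_specs() -> dict[str, DistributionSpec]:
    """Distribution specs attached to the base-case parameter set."""
    return {
        "p_confirm_completion": DistributionSpec("beta", 0.2775, relative_range=0.20),
        "n_confirmed_by_severity": DistributionSpec(
            "dirichlet", (118 / 172, 41 / 172, 13 / 172)
        ),
        "p_brace_init": DistributionSpec("beta", 0.90244, relative_range=0.20),
        "p_mild_to_mod_cycle": DistributionSpec("beta", 0.0164, relative_range=0.50),
        "p_mod_to_sev_nobrace_cycle": DistributionSpec(
            "beta", 0.0877, relative_range=0.50
        ),
        "hr_brace": DistributionSpec("lognormal", 0.45, low=0.30, high=0.80),
        "p_surgery_annual": DistributionSpec("beta", 0.90, low=0.70, high=0.98),
        "u_mild": DistributionSpec("beta", 0.95, low=0.90, high=0.99),
        "u_mod_nobrace": DistributionSpec("beta", 0.95, low=0.90, high=0.99),
        "u_mod_brace": DistributionSpec("beta", 0.87, low=0.80, high=0.93),
        "u_sev": DistributionSpec("beta", 0.76, low=0.65, high=0.82),
        "u_post": DistributionSpec("beta", 0.82, low=0.75, high=0.90),
        "c_screen_total": DistributionSpec("gamma", 9269.0676, relative_range=0.20),
        "c_xray": DistributionSpec("gamma", 50.544, relative_range=0.20),
        "c_brace": DistributionSpec("gamma", 772.2, relative_range=0.20),
        "c_fu_screen_cycle": DistributionSpec("gamma", 52.5096, relative_range=0.20),
        "c_fu_noscreen_cycle": DistributionSpec("gamma", 26.2548, relative_range=0.20),
        "c_surgery": DistributionSpec("gamma", 1965.60, relative_range=0.20),
        "theta_miss": DistributionSpec("beta", 0.30, low=0.15, high=0.50),
        "pi_init_noscreen": DistributionSpec("dirichlet", (0.235, 0.521, 0.244)),
    }


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameterization of the decision-tree + Markov model.

    Counts and cascade probabilities come from the screening program
    (52,678 screened; 1,211 suspected; 27.75% completing radiography; 172
    confirmed split 118/41/13 mild/moderate/severe; 90.2% of moderate cases
    braced).  Quarterly transition probabilities follow the constant-hazard
    conversions in :mod:`scoliscreen.hazards`; the two derived per-cycle
    probabilities (braced moderate-to-severe progression and
    severe-to-surgery) default to ``None`` and are filled by
    :meth:`with_derived`.
    """

    # --- screening cascade -------------------------------------------------
    n_screened: float = 52678.0
    n_suspected: float = 1211.0
    p_confirm_completion: float = 0.2775
    n_confirmed_by_severity: tuple[float, float, float] = (118.0, 41.0, 13.0)
    p_brace_init: float = 0.90244

    # --- quarterly natural history / intervention effect -------------------
    p_mild_to_mod_cycle: float = 0.0164
    p_mod_to_sev_nobrace_cycle: float = 0.0877
    hr_brace: float = 0.45
    p_mod_to_sev_brace_cycle: float | None = None  # derived
    p_surgery_annual: float = 0.90
    p_sev_to_surg_cycle: float | None = None  # derived

    # --- utilities (per year of full health) -------------------------------
    u_noais: float = 1.0
    u_mild: float = 0.95
    u_mod_nobrace: float = 0.95
    u_mod_brace: float = 0.87
    u_sev: float = 0.76
    u_post: float = 0.82

    # --- costs (US$) --------------------------------------------------------
    c_screen_total: float = 9269.0676
    c_xray: float = 50.544
    c_brace: float = 772.2
    c_fu_screen_cycle: float = 52.5096
    c_fu_noscreen_cycle: float = 26.2548
    c_surgery: float = 1965.60

    # --- discounting / horizon / threshold ----------------------------------
    r_discount: float = 0.05
    cycle_years: float = 0.25
    horizon_cycles: int = 16
    wtp: float = 7416.63
    fx_rate: float = 0.1404

    # --- no-screening (opportunistic detection) arm --------------------------
    theta_miss: float = 0.30
    pi_init_noscreen: tuple[float, float, float] = (0.235, 0.521, 0.244)

    # --- switches ------------------------------------------------------------
    #: undiagnosed individuals reaching the severe state present clinically
    #: and enter the (diagnosed) surgical pathway
    clinical_presentation_at_severe: bool = True
    dirichlet_ess: float = 172.0

    specs: Mapping[str, DistributionSpec] = field(
        default_factory=_base_specs, compare=False, repr=False
    )

    # -- derived views --------------------------------------------------------

    @property
    def n_confirmed_total(self) -> float:
        return float(sum(self.n_confirmed_by_severity))

    @property
    def severity_props(self) -> tuple[float, float, float]:
        """Mild/moderate/severe proportions among confirmed cases."""
        total = self.n_confirmed_total
        if total <= 0:
            return (0.0, 0.0, 0.0)
        return tuple(c / total for c in self.n_confirmed_by_severity)  # type: ignore[return-value]

    @property
    def horizon_years(self) -> float:
        return self.horizon_cycles * self.cycle_years

    @property
    def currency(self) -> CurrencyConvention:
        return CurrencyConvention(fx_rate=self.fx_rate)

    def with_derived(self) -> "ModelParameters":
        """Fill the derived per-cycle probabilities if unset.

        Braced moderate-to-severe progression applies the bracing hazard
        ratio to the unbraced per-cycle probability on the hazard scale;
        the per-cycle severe-to-surgery probability rescales the annual
        0.90 surgery probability to the 3-month cycle under a constant
        hazard.
        """
        from . import hazards

        changes: dict[str, float] = {}
        if self.p_mod_to_sev_brace_cycle is None:
            changes["p_mod_to_sev_brace_cycle"] = hazards.apply_hazard_ratio(
                self.p_mod_to_sev_nobrace_cycle, self.hr_brace
            )
        if self.p_sev_to_surg_cycle is None:
            changes["p_sev_to_surg_cycle"] = hazards.convert_prob_timescale(
                self.p_surgery_annual, 1.0, self.cycle_years
            )
        if not changes:
            return self
        return dataclasses.replace(self, **changes)

    # -- validation ------------------------------------------------------------

    def validate(self) -> "ModelParameters":
        """Raise :class:`ParameterError` naming the first offending field."""
        probs = {
            "p_confirm_completion": self.p_confirm_completion,
            "p_brace_init": self.p_brace_init,
            "p_mild_to_mod_cycle": self.p_mild_to_mod_cycle,
            "p_mod_to_sev_nobrace_cycle": self.p_mod_to_sev_nobrace_cycle,
            "p_surgery_annual": self.p_surgery_annual,
            "theta_miss": self.theta_miss,
        }
        if self.p_mod_to_sev_brace_cycle is not None:
            probs["p_mod_to_sev_brace_cycle"] = self.p_mod_to_sev_brace_cycle
        if self.p_sev_to_surg_cycle is not None:
            probs["p_sev_to_surg_cycle"] = self.p_sev_to_surg_cycle
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name}={value} outside [0, 1]")
        for name in ("u_noais", "u_mild", "u_mod_nobrace", "u_mod_brace", "u_sev", "u_post"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name}={value} outside [0, 1]")
        for name in (
            "c_screen_total", "c_xray", "c_brace",
            "c_fu_screen_cycle", "c_fu_noscreen_cycle", "c_surgery", "wtp",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ParameterError(f"{name}={value} must be >= 0")
        if self.hr_brace <= 0:
            raise ParameterError(f"hr_brace={self.hr_brace} must be > 0")
        if self.fx_rate <= 0:
            raise ParameterError(f"fx_rate={self.fx_rate} must be > 0")
        if self.r_discount <= -1:
            raise ParameterError(f"r_discount={self.r_discount} must be > -1")
        if self.cycle_years <= 0:
            raise ParameterError(f"cycle_years={self.cycle_years} must be > 0")
        if self.horizon_cycles < 1:
            raise ParameterError(f"horizon_cycles={self.horizon_cycles} must be >= 1")
        if self.n_screened <= 0:
            raise ParameterError(f"n_screened={self.n_screened} must be > 0")
        for name in ("n_suspected",):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if any(c < 0 for c in self.n_confirmed_by_severity):
            raise ParameterError("n_confirmed_by_severity entries must be >= 0")
        pi = np.asarray(self.pi_init_noscreen, dtype=float)
        if pi.shape != (3,) or (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"pi_init_noscreen={self.pi_init_noscreen} must be a probability "
                "triple summing to 1"
            )
        return self


# tuple-valued config keys
_TUPLE_FIELDS = {"n_confirmed_by_severity", "pi_init_noscreen"}
_FIELD_NAMES = {
    f.name for f in dataclasses.fields(ModelParameters) if f.name != "specs"
}


def default_parameters() -> ModelParameters:
    """The base-case parameter set, derived per-cycle probabilities unset."""
    return ModelParameters()


def literature_parameters() -> ModelParameters:
    """Alternative parameter set taken from the literature-sourced tables.

    Differs from the base case in the bracing hazard ratio (0.52), the
    unbraced quarterly progression probability (0.083), an explicitly
    stated per-cycle severe-to-surgery probability (0.206), the utility
    set (0.96/0.93/0.89/0.91/0.86), and lightly rounded unit costs.
    """
    specs = _base_specs()
    specs.update(
        {
            "p_mild_to_mod_cycle": DistributionSpec("beta", 0.016, relative_range=0.50),
            "p_mod_to_sev_nobrace_cycle": DistributionSpec(
                "beta", 0.083, relative_range=0.50
            ),
            "hr_brace": DistributionSpec("lognormal", 0.52, low=0.30, high=0.80),
            "u_mild": DistributionSpec("beta", 0.96, low=0.91, high=1.0),
            "u_mod_nobrace": DistributionSpec("beta", 0.93, low=0.88, high=0.98),
            "u_mod_brace": DistributionSpec("beta", 0.89, low=0.84, high=0.94),
            "u_sev": DistributionSpec("beta", 0.91, low=0.86, high=0.96),
            "u_post": DistributionSpec("beta", 0.86, low=0.81, high=0.91),
        }
    )
    return ModelParameters(
        p_mild_to_mod_cycle=0.016,
        p_mod_to_sev_nobrace_cycle=0.083,
        hr_brace=0.52,
        p_sev_to_surg_cycle=0.206,
        u_mild=0.96,
        u_mod_nobrace=0.93,
        u_mod_brace=0.89,
        u_sev=0.91,
        u_post=0.86,
        c_screen_total=9269.06,
        c_xray=50.54,
        c_fu_screen_cycle=52.51,
        c_fu_noscreen_cycle=26.25,
        specs=specs,
    )


def load_parameters(config_text: str | None) -> ModelParameters:
    """Parse a flat ``key: value`` YAML configuration into parameters.

    Missing keys fall back to the base case; unknown keys are rejected;
    invariant violations name the offending field.  An empty configuration
    returns :func:`default_parameters`.
    """
    if config_text is None or not config_text.strip():
        return default_parameters()
    try:
        data = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ParameterError(f"configuration failed to parse: {exc}") from exc
    if data is None:
        return default_parameters()
    if not isinstance(data, Mapping):
        raise ParameterError("configuration must be a flat key: value mapping")
    overrides: dict[str, object] = {}
    for key, value in data.items():
        if key not in _FIELD_NAMES:
            raise ParameterError(f"unknown configuration key {key!r}")
        if key in _TUPLE_FIELDS:
            if not isinstance(value, Iterable):
                raise ParameterError(f"{key} must be a 3-element sequence")
            value = tuple(float(v) for v in value)
            if len(value) != 3:
                raise ParameterError(f"{key} must have exactly 3 elements")
        elif key == "horizon_cycles":
            value = int(value)
        elif key == "clinical_presentation_at_severe":
            value = bool(value)
        else:
            value = float(value)
        overrides[key] = value
    params = dataclasses.replace(default_parameters(), **overrides)
    return params.validate()
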