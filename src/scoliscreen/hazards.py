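"""Constant-hazard conversions between rates, probabilities and timescales.

Under a constant hazard r, the probability of an event within t years is
p = 1 - exp(-r t).  These exact exponential formulas (never the linear
p/4 approximation) are used for every timescale change and for applying
the bracing hazard ratio to a per-cycle progression probability.
"""

from __future__ import annotations

import math

__all__ = [
    "prob_to_rate",
    "rate_to_prob",
    "convert_prob_timescale",
    "apply_hazard_ratio",
]


def prob_to_rate(p: float, t: float) -> float:
    """Constant hazard (events/year) implied by probability ``p`` over ``t`` years."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability {p} must lie in [0, 1)")
    if t <= 0:
        raise ValueError(f"horizon {t} must be positive")
    return -math.log1p(-p) / t


def rate_to_prob(r: float, t: float) -> float:
    """Probability of an event within ``t`` years at constant hazard ``r``."""
    if r < 0:
        raise ValueError(f"rate {r} must be nonnegative")
    if t <= 0:
        raise ValueError(f"horizon {t} must be positive")
    return -math.expm1(-r * t)


def convert_prob_timescale(p: float, t_from: float, t_to: float) -> float:
    """Re-express probability ``p`` over ``t_from`` years on a ``t_to``-year scale.

    Equivalent to ``rate_to_prob(prob_to_rate(p, t_from), t_to)`` but computed
    as ``1 - (1-p)**(t_to/t_from)`` for numerical stability.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability {p} must lie in [0, 1)")
    if t_from <= 0 or t_to <= 0:
        raise ValueError("timescales must be positive")
    return -math.expm1((t_to / t_from) * math.log1p(-p))


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Apply hazard ratio ``hr`` to per-cycle probability ``p``.

    Scaling the constant hazard by ``hr`` over the same cycle gives
    ``1 - (1-p)**hr``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability {p} must lie in [0, 1)")
    if hr <= 0:
        raise ValueError(f"hazard ratio {hr} must be positive")
    return -math.expm1(hr * math.log1p(-p))
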