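"""Model / Results objects wrapping the full screening cost-utility analysis.

`ScreeningCUA` is constructed from a parameter set (or a configuration
file, or observed cascade counts); `fit()` evaluates both strategy arms
deterministically and returns a `ScreeningCUAResults` carrying the
per-arm economics, the incremental comparison, and entry points for the
sensitivity, scenario and calibration analyses.

Example
-------
>>> from scoliscreen import ScreeningCUA
>>> res = ScreeningCUA().fit()
>>> print(res.summary())            # doctest: +SKIP
>>> psa = res.psa(n_iter=3000, seed=1)
"""

from __future__ import annotations

from pathlib import Path

from . import calibration as _calibration
from . import uncertainty as _uncertainty
from .cascade import CascadeCounts, parameters_from_counts
from .economics import ComparisonResult
from .markov import ArmResult, run_arm
from .parameters import (
    DEFAULT_SEED,
    ModelParameters,
    default_parameters,
    load_parameters,
)

__all__ = ["ScreeningCUA", "ScreeningCUAResults"]


class ScreeningCUA:
    """Decision-tree + Markov cohort model of school scoliosis screening.

    Parameters
    ----------
    params : ModelParameters, optional
        Full parameter set; defaults to the base case.
    """

    def __init__(self, params: ModelParameters | None = None):
        self.params = (params or default_parameters()).with_derived().validate()

    @classmethod
    def from_config(cls, source: str | Path) -> "ScreeningCUA":
        """Build from a flat ``key: value`` configuration file or text."""
        path = Path(source)
        text = path.read_text() if path.is_file() else str(source)
        return cls(load_parameters(text))

    @classmethod
    def from_counts(
        cls, counts: CascadeCounts, base: ModelParameters | None = None
    ) -> "ScreeningCUA":
        """Build from observed screening-cascade counts."""
        return cls(parameters_from_counts(counts, base))

    def fit(self, wtp: float | None = None) -> "ScreeningCUAResults":
        """Deterministic evaluation of both strategy arms."""
        wtp = self.params.wtp if wtp is None else wtp
        screening = run_arm(self.params, "screening")
        no_screening = run_arm(self.params, "no_screening")
        from .economics import compare

        return ScreeningCUAResults(
            model=self,
            screening=screening,
            no_screening=no_screening,
            comparison=compare(screening, no_screening, wtp),
        )


class ScreeningCUAResults:
    """Fitted base case plus handles for the uncertainty analyses."""

    def __init__(
        self,
        model: ScreeningCUA,
        screening: ArmResult,
        no_screening: ArmResult,
        comparison: ComparisonResult,
    ):
        self.model = model
        self.params = model.params
        self.screening = screening
        self.no_screening = no_screening
        self.comparison = comparison

    def summary(self, currency: str = "USD") -> str:
        """Base-case result table (strategies plus increment)."""
        from .report import format_comparison

        return format_comparison(
            self.comparison, currency=currency, fx_rate=self.params.fx_rate
        )

    # ---- uncertainty -----------------------------------------------------

    def owsa(self, wtp: float | None = None) -> list["_uncertainty.TornadoEntry"]:
        """One-way (tornado) sensitivity analysis on the INMB."""
        return _uncertainty.owsa(self.params, wtp)

    def psa(
        self,
        n_iter: int = 3000,
        seed: int = DEFAULT_SEED,
        wtp: float | None = None,
    ) -> "_uncertainty.PsaSummary":
        """Probabilistic sensitivity analysis (Monte-Carlo over parameters)."""
        return _uncertainty.run_psa(self.params, n_iter=n_iter, seed=seed, wtp=wtp)

    def scenario(
        self,
        name: str | None = None,
        overrides: dict[str, object] | None = None,
        wtp: float | None = None,
    ) -> ComparisonResult:
        """Deterministic scenario run (named ``"A"``/``"B"`` or overrides)."""
        merged: dict[str, object] = {}
        if name is not None:
            try:
                merged.update(_uncertainty.SCENARIOS[name])
            except KeyError:
                raise KeyError(
                    f"unknown scenario {name!r}; available: "
                    f"{sorted(_uncertainty.SCENARIOS)}"
                ) from None
        merged.update(overrides or {})
        return _uncertainty.run_scenario(self.params, merged, wtp)

    def calibrate(
        self, anchors: "_calibration.AnchorSet | None" = None
    ) -> "_calibration.CalibrationResult":
        """Maximum-likelihood calibration of the no-screening arm."""
        anchors = anchors or _calibration.AnchorSet()
        return _calibration.calibrate_no_screening(self.params, anchors)
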