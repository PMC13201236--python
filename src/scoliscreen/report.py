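"""Report-layer formatting: result tables, currency rendering, manifests.

Currency is rounded to 2 decimal places and QALYs to 6 only here; the
computational layers never round.  Renminbi figures divide the US-dollar
amounts by the exchange rate; by default the division is applied to the
already-rounded dollar figures (matching how published tables chain their
conversions), with ``round_through=False`` converting unrounded values
instead.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .economics import ComparisonResult

__all__ = ["comparison_frame", "format_comparison", "RunManifest"]

_ROW_LABELS = [
    "Universal screening arm",
    "No active screening control arm",
    "Increment",
]


def comparison_frame(
    result: ComparisonResult,
    currency: str = "USD",
    fx_rate: float = 0.1404,
    round_through: bool = True,
) -> pd.DataFrame:
    """Three-row result table: the two strategies and their increment."""
    if currency not in {"USD", "CNY"}:
        raise ValueError("currency must be USD or CNY")
    cost = [result.cost_screen, result.cost_none, result.delta_cost]
    qaly = [result.qaly_screen, result.qaly_none, result.delta_qaly]
    nmb = [result.nmb_screen, result.nmb_none, result.inmb]
    if currency == "CNY":
        if round_through:
            cost = [round(round(c, 2) / fx_rate, 2) for c in cost]
            nmb = [round(round(v, 2) / fx_rate, 2) for v in nmb]
        else:
            cost = [round(c / fx_rate, 2) for c in cost]
            nmb = [round(v / fx_rate, 2) for v in nmb]
    else:
        cost = [round(c, 2) for c in cost]
        nmb = [round(v, 2) for v in nmb]
    frame = pd.DataFrame(
        {
            "strategy": _ROW_LABELS,
            f"cost_{currency.lower()}": cost,
            "qaly": [round(q, 6) for q in qaly],
            f"nmb_{currency.lower()}": nmb,
        }
    )
    return frame


def format_comparison(
    result: ComparisonResult,
    currency: str = "USD",
    fx_rate: float = 0.1404,
    round_through: bool = True,
) -> str:
    """Plain-text rendering of :func:`comparison_frame` plus the verdict."""
    frame = comparison_frame(result, currency, fx_rate, round_through)
    lines = [
        f"Cost-utility results ({currency} per person, discounted; "
        f"WTP = {result.wtp:.2f} US$/QALY)",
        frame.to_string(index=False),
    ]
    if result.dominance is not None:
        lines.append(f"Verdict: screening is {result.dominance}")
    elif result.icer is not None:
        lines.append(f"ICER: {result.icer:.2f} US$/QALY")
    return "\n".join(lines)


@dataclass(frozen=True)
class RunManifest:
    """Provenance stamp written next to every CLI output."""

    command: str
    config_digest: str
    seed: int
    timestamp: str
    version: str

    @classmethod
    def create(cls, command: str, config_text: str | None, seed: int) -> "RunManifest":
        from . import __version__

        digest = hashlib.sha256((config_text or "").encode()).hexdigest()[:16]
        return cls(
            command=command,
            config_digest=digest,
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            version=__version__,
        )

    def write(self, directory: Path) -> Path:
        path = Path(directory) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n")
        return path
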