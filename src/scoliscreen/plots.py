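"""Convenience plots: cost-utility plane, CEAC, tornado diagram.

All functions draw on a provided or fresh matplotlib Axes and return it;
figure export is left to the caller.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .uncertainty import PsaSummary, TornadoEntry

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado"]


def plot_ce_plane(summary: PsaSummary, ax=None):
    """Scatter of PSA draws on the (incremental QALY, incremental cost) plane."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(
        summary.draws["delta_qaly"], summary.draws["delta_cost"], s=4, alpha=0.4
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs per person")
    ax.set_ylabel("Incremental cost (US$ per person)")
    ax.set_title(f"Cost-utility plane ({summary.n_iter} draws)")
    return ax


def plot_ceac(curve: list[tuple[float, float]], ax=None):
    """Probability cost-effective as a function of the WTP threshold."""
    if ax is None:
        _, ax = plt.subplots()
    wtp, prob = zip(*curve)
    ax.plot(wtp, prob)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness-to-pay (US$/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title("Cost-effectiveness acceptability curve")
    return ax


def plot_tornado(entries: list[TornadoEntry], base_inmb: float, ax=None, top: int = 12):
    """Horizontal-bar tornado of INMB ranges, widest spans on top."""
    if ax is None:
        _, ax = plt.subplots()
    shown = entries[:top][::-1]
    names = [e.parameter_name for e in shown]
    for i, e in enumerate(shown):
        lo, hi = sorted((e.inmb_low, e.inmb_high))
        ax.barh(i, hi - lo, left=lo, color="steelblue")
    ax.axvline(base_inmb, color="black", lw=1.0)
    ax.set_yticks(range(len(shown)), names)
    ax.set_xlabel("Incremental net monetary benefit (US$ per person)")
    ax.set_title("One-way sensitivity analysis")
    return ax
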