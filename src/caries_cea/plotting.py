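"""Figures: acceptability curves and the cost-effectiveness plane."""

from __future__ import annotations

from pathlib import Path

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .psa import CEACCurve, PSASamples


def _save(fig: Figure, path) -> Path:
    path = Path(path)
    FigureCanvasAgg(fig)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    return path


def plot_ceac(curve: CEACCurve, path) -> Path:
    """Acceptability curves: P(highest NMB) versus WTP, one line per arm."""
    fig = Figure(figsize=(7, 4.5))
    ax = fig.add_subplot()
    for arm in curve.probabilities.columns:
        ax.plot(curve.wtp_grid, curve.probabilities[arm], label=arm)
    ax.set_xlabel("Willingness to pay (ZAR per DMFT averted)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    ax.set_title("Cost-effectiveness acceptability curves")
    return _save(fig, path)


def plot_ce_plane(samples: PSASamples, path) -> Path:
    """Scatter of the Monte Carlo (DMFT averted, cost) cloud per arm."""
    fig = Figure(figsize=(7, 4.5))
    ax = fig.add_subplot()
    for j, arm in enumerate(samples.arms):
        ax.scatter(
            samples.dmft_averted[:, j],
            samples.costs[:, j],
            s=4,
            alpha=0.4,
            label=arm,
        )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("DMFT averted vs do-nothing")
    ax.set_ylabel("Total discounted cost (ZAR)")
    ax.legend(fontsize=8, markerscale=2)
    ax.set_title("Cost-effectiveness plane")
    return _save(fig, path)
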