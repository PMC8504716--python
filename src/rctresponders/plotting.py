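"""Four-panel view of a responder-proportion sweep.

Panels: ethical-loss share, sample size, relative risk, and chi-square,
each against the proportion of responders in the sample.
"""

from __future__ import annotations

from pathlib import Path

from .sweep import SweepRow

__all__ = ["plot_sweep"]


def plot_sweep(rows: list[SweepRow], path: str | Path | None = None):
    """Plot the four trial characteristics against responder proportion.

    Returns the matplotlib Figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(rows, key=lambda r: r.p)
    p = [r.p * 100 for r in ordered]
    panels = [
        ("A. Ethical losses (% of sample)", [r.ethical_loss_pct for r in ordered]),
        ("B. Trial sample size", [r.N for r in ordered]),
        ("C. Observed relative risk", [r.RR for r in ordered]),
        ("D. Chi-square", [r.chi2 for r in ordered]),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), constrained_layout=True)
    for ax, (title, y) in zip(axes.flat, panels):
        ax.plot(p, y, marker="o", ms=3, lw=1)
        ax.set_title(title, fontsize=10)
        ax.set_xlabel("% responders in sample")
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
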