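"""Quick-look figures for chamber traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .permeability import PermeabilityTrace, SlopeFit


def plot_trace(
    trace: PermeabilityTrace, fit: SlopeFit | None = None, path: str | Path | None = None
):
    """Normalized MFI vs time for one chamber, with the fitted line."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(trace.times_hours, trace.normalized_mfi, "o-", ms=3, label="normalized MFI")
    if fit is not None:
        ax.plot(
            trace.times_hours,
            fit.intercept + fit.m * trace.times_hours,
            "--",
            label=f"m = {fit.m:.3f}/h (R² = {fit.r_squared:.3f})",
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized MFI")
    title = trace.chamber_id or "chamber"
    if trace.condition:
        title += f" [{trace.condition}]"
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
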