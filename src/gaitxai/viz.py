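"""Plotting of spatially averaged signals, relevance curves and events."""
from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .interpret import CycleSegmentation, EventAssignment, SACurve
from .phase import GaitPhaseModel


def plot_sa_with_events(
    signal_sa: SACurve,
    relevance_sa: Optional[SACurve] = None,
    segmentation: Optional[CycleSegmentation] = None,
    assignment: Optional[EventAssignment] = None,
    phase_model: Optional[GaitPhaseModel] = None,
    out_path: Optional[str] = None,
    title: str = "",
):
    """Signal SA (black) over relevance SA (blue) with cycle/event marks.

    Saves SVG/PNG when ``out_path`` is given; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = 2 if relevance_sa is not None else 1
    fig, axes = plt.subplots(n_rows, 1, sharex=True, figsize=(9, 2.6 * n_rows))
    axes = np.atleast_1d(axes)
    axes[0].plot(signal_sa.values, color="black", lw=1)
    axes[0].set_ylabel("signal SA")
    if relevance_sa is not None:
        axes[1].plot(relevance_sa.values, color="tab:blue", lw=1)
        axes[1].set_ylabel("relevance SA")
    if segmentation is not None:
        for b in segmentation.cycle_boundaries:
            for ax in axes:
                ax.axvline(b, color="gray", ls=":", lw=0.8)
    if assignment is not None:
        for frame, _, event, score in assignment.peaks:
            axes[-1].axvline(frame, color="red", lw=1)
            axes[-1].annotate(event, (frame, score), color="red")
    axes[-1].set_xlabel("frame")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path)
        plt.close(fig)
    return fig
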