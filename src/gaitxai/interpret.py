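"""Gait-cycle interpretation of signals and relevance maps.

Converts windowed signals and relevance heatmaps into gait-cycle terms:
the per-frame spatial average SA[n] = (1/C) * sum_i x_i[n] across the C
sensor channels, heel-strike based cycle segmentation, and assignment of
relevance peaks to the named gait events A-G via their phase within the
cycle. Aggregating per-class top-peak labels yields the "class k's modal
event is E_k" statements the pipeline exists to produce.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .phase import GaitPhaseModel, phase_to_event

__all__ = [
    "SACurve", "CycleSegmentation", "EventAssignment",
    "spatial_average", "segment_cycles", "assign_relevance_events",
    "event_histogram", "LEFT_FOOT_CHANNELS",
]

#: Sensor-channel indices of the reference (left) foot in processed
#: 18-channel insole windows (L1..L8).
LEFT_FOOT_CHANNELS = tuple(range(8))


@dataclass
class SACurve:
    """Spatially averaged per-frame curve of one window."""

    values: np.ndarray
    source: str = "signal"  # "signal" | "relevance"
    n_channels_averaged: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class CycleSegmentation:
    """Detected heel strikes of the reference foot and complete cycles."""

    cycle_boundaries: np.ndarray  # strictly increasing frame indices
    complete_cycles: List[Tuple[int, int]]  # [start, end) frame intervals
    sample_rate: float = 100.0


@dataclass
class EventAssignment:
    """Relevance peaks labeled with gait events."""

    peaks: List[Tuple[int, float, str, float]]  # (frame, phase, event, score)
    cycle_indices: List[int] = field(default_factory=list)
    degenerate: bool = False  # set when no usable peaks exist


def _smooth(v: np.ndarray, width: int) -> np.ndarray:
    """Edge-normalized moving average (constant curves stay constant)."""
    if width <= 1:
        return v
    kern = np.ones(width)
    return np.convolve(v, kern, mode="same") / np.convolve(
        np.ones_like(v), kern, mode="same"
    )


def spatial_average(matrix: np.ndarray, source: str = "signal",
                    channels: Optional[Sequence[int]] = None) -> SACurve:
    """Per-frame arithmetic mean across sensor channels.

    ``matrix`` is (frames, channels); the divisor is the actual channel
    count (18 insole / 116 optical, or the selected subset).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("expected a non-empty (frames, channels) matrix")
    if channels is not None:
        m = m[:, list(channels)]
    return SACurve(m.mean(axis=1), source=source, n_channels_averaged=m.shape[1])


def segment_cycles(
    sa: SACurve,
    sample_rate: float,
    threshold_frac: float = 0.2,
    refractory_s: float = 0.5,
    onset_frac: float = 0.02,
    min_cycle_s: float = 0.5,
    max_cycle_s: float = 2.0,
) -> CycleSegmentation:
    """Detect heel strikes as upward crossings of a relative threshold.

    The threshold is ``threshold_frac`` of the curve's range above its
    minimum (so the segmentation is invariant to amplitude scaling); a
    refractory period of ``refractory_s`` suppresses re-triggering inside a
    cycle, and each accepted crossing is refined by walking back to where
    the curve last rose above ``onset_frac`` of the range, which lands the
    boundary at the force onset rather than at the threshold crossing.
    Only complete cycles with plausible duration (``min_cycle_s`` to
    ``max_cycle_s``) are returned.
    """
    v = _smooth(sa.values, 3)  # light smoothing stabilizes onset refinement
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        warnings.warn("constant signal: no cycles detected")
        return CycleSegmentation(np.array([], dtype=int), [], sample_rate)
    r = (v - lo) / (hi - lo)
    th = threshold_frac
    refractory = int(round(refractory_s * sample_rate))
    boundaries: List[int] = []
    last = -refractory - 1
    for i in range(1, len(r)):
        if r[i - 1] < th <= r[i] and i - last > refractory:
            j = i
            while j > 0 and r[j - 1] > onset_frac:
                j -= 1
            boundaries.append(j)
            last = i
    boundaries = sorted(set(boundaries))
    if len(boundaries) < 2:
        warnings.warn("fewer than 2 heel strikes detected; no complete cycles")
        return CycleSegmentation(np.asarray(boundaries, dtype=int), [], sample_rate)
    cycles = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        dur = (b - a) / sample_rate
        if min_cycle_s <= dur <= max_cycle_s:
            cycles.append((a, b))
    return CycleSegmentation(np.asarray(boundaries, dtype=int), cycles, sample_rate)


def assign_relevance_events(
    relevance_sa: SACurve,
    segmentation: CycleSegmentation,
    phase_model: Optional[GaitPhaseModel] = None,
    top_k: int = 1,
    smooth_width: int = 3,
) -> EventAssignment:
    """Label the strongest relevance peaks inside complete cycles.

    Peaks are local maxima of the lightly smoothed relevance SA (moving
    average of ``smooth_width`` frames, suppressing single-frame noise).
    Each peak's frame is converted to a phase fraction within its cycle and
    labeled via the phase->event map. Returns the ``top_k`` peaks by
    score; a flat curve yields an empty, flagged assignment.
    """
    phase_model = phase_model or GaitPhaseModel()
    if not segmentation.complete_cycles:
        return EventAssignment([], [], degenerate=True)
    v = _smooth(relevance_sa.values, smooth_width)
    if np.ptp(v) == 0:
        return EventAssignment([], [], degenerate=True)
    candidates: List[Tuple[int, float, str, float, int]] = []
    for ci, (a, b) in enumerate(segmentation.complete_cycles):
        seg = v[a:b]
        idx, _ = find_peaks(seg)
        # peaks at the cycle edges count too (a maximum may sit at a boundary)
        if seg.size and seg.argmax() not in idx and (seg.argmax() in (0, seg.size - 1)):
            idx = np.append(idx, seg.argmax())
        for i in idx:
            frame = a + int(i)
            phase = (frame - a) / (b - a)
            candidates.append((frame, phase, phase_to_event(phase, phase_model),
                               float(seg[i]), ci))
    if not candidates:
        return EventAssignment([], [], degenerate=True)
    candidates.sort(key=lambda c: -c[3])
    chosen = candidates[:top_k]
    return EventAssignment(
        peaks=[(f, p, e, s) for f, p, e, s, _ in chosen],
        cycle_indices=[ci for *_, ci in chosen],
    )


def event_histogram(
    assignments: Dict[object, Sequence[EventAssignment]]
) -> Dict[object, Dict[str, float]]:
    """Per-class normalized frequency of top-1 peak event labels.

    ``assignments`` maps a class label to the per-window assignments of its
    (true-positive) samples; windows without usable peaks are skipped.
    Classes with no usable windows are omitted with a warning.
    """
    out: Dict[object, Dict[str, float]] = {}
    for cls, items in assignments.items():
        labels = [a.peaks[0][2] for a in items if a.peaks]
        if not labels:
            warnings.warn(f"class {cls!r} has no usable event assignments; omitted")
            continue
        counts: Dict[str, float] = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        total = sum(counts.values())
        out[cls] = {k: v / total for k, v in sorted(counts.items())}
    return out
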