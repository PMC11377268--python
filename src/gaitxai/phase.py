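"""Gait-cycle phase model.

One gait cycle runs from a heel strike of the reference foot to its next
heel strike. The cycle is split into a stance phase (foot on the ground,
~60% of the cycle) and a swing phase (~40%), and further into seven named
intervals:

====  ================  ==========================================
A     Heel strike       initial ground contact of the reference heel
B     Loading response  foot flat, weight transfer onto the limb
C     Mid-stance        single support, opposite limb in swing
D     Terminal stance   heel rise, preparation for opposite strike
E     Pre-swing         second double support, ends with toe-off
F     Initial/mid-swing toe-off into single support and swing
G     Terminal swing    limb extends forward, ready for heel strike
====  ================  ==========================================

Events A-E make up stance and end exactly at the stance fraction; F-G make
up swing. Event boundaries are expressed as fractions of one cycle, so the
same model serves recordings at any sample rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

EVENT_LABELS = ("A", "B", "C", "D", "E", "F", "G")

#: Default event intervals as fractions of one cycle. Durations inside the
#: stance/swing split follow standard clinical gait-phase conventions scaled
#: to a 60/40 stance/swing split.
DEFAULT_EVENT_BOUNDARIES: Dict[str, Tuple[float, float]] = {
    "A": (0.00, 0.02),
    "B": (0.02, 0.10),
    "C": (0.10, 0.30),
    "D": (0.30, 0.50),
    "E": (0.50, 0.60),
    "F": (0.60, 0.87),
    "G": (0.87, 1.00),
}

#: Last stance event; its interval must end exactly at ``stance_fraction``.
LAST_STANCE_EVENT = "E"


@dataclass(frozen=True)
class GaitPhaseModel:
    """Timing model of one gait cycle.

    Parameters
    ----------
    cycle_duration : float
        Subject-level mean duration of one full cycle in seconds.
    stance_fraction : float
        Fraction of the cycle spent in stance, in (0, 1).
    event_boundaries : dict
        Ordered map event label (A..G) -> [lo, hi) phase interval as
        fractions of one cycle. Intervals must be disjoint, ordered A->G
        and cover [0, 1); stance events A-E must end at
        ``stance_fraction``.
    cadence_jitter_sd : float
        Relative standard deviation of per-cycle duration fluctuations.
    foot_phase_offset : float
        Phase offset of the contralateral foot, as a fraction of the
        cycle (0.5 for symmetric alternating gait).
    """

    cycle_duration: float = 1.0
    stance_fraction: float = 0.60
    event_boundaries: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_BOUNDARIES)
    )
    cadence_jitter_sd: float = 0.02
    foot_phase_offset: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")
        labels = tuple(self.event_boundaries)
        if labels != EVENT_LABELS:
            raise ValueError(
                f"event_boundaries must contain exactly {EVENT_LABELS} in order, "
                f"got {labels}"
            )
        cursor = 0.0
        for label, (lo, hi) in self.event_boundaries.items():
            if abs(lo - cursor) > 1e-12 or hi <= lo:
                raise ValueError(
                    "event intervals must be contiguous, ordered and non-empty; "
                    f"offending event {label!r}: [{lo}, {hi}) after {cursor}"
                )
            cursor = hi
        if abs(cursor - 1.0) > 1e-12:
            raise ValueError("event intervals must cover [0, 1)")
        stance_end = self.event_boundaries[LAST_STANCE_EVENT][1]
        if abs(stance_end - self.stance_fraction) > 1e-9:
            raise ValueError(
                f"stance events A-{LAST_STANCE_EVENT} must end at "
                f"stance_fraction={self.stance_fraction}, got {stance_end}"
            )

    def event_interval(self, label: str) -> Tuple[float, float]:
        try:
            return self.event_boundaries[label]
        except KeyError:
            raise KeyError(f"unknown gait event {label!r}; expected one of {EVENT_LABELS}")


def phase_to_event(phase: float, phase_model: GaitPhaseModel) -> str:
    """Return the gait event label whose interval contains ``phase``.

    ``phase`` must lie in [0, 1). The intervals partition the cycle, so the
    mapping is total and single-valued.
    """
    if not 0.0 <= phase < 1.0:
        raise ValueError(f"phase must lie in [0, 1), got {phase}")
    for label, (lo, hi) in phase_model.event_boundaries.items():
        if lo <= phase < hi:
            return label
    # unreachable by construction (intervals cover [0, 1))
    raise AssertionError("event intervals failed to cover the phase")


def scaled_boundaries(stance_fraction: float) -> Dict[str, Tuple[float, float]]:
    """Rescale the default event map to an arbitrary stance fraction.

    The relative proportions of events inside stance (A-E) and inside swing
    (F-G) are preserved while the stance/swing split is moved to
    ``stance_fraction``.
    """
    default_stance = DEFAULT_EVENT_BOUNDARIES[LAST_STANCE_EVENT][1]
    out: Dict[str, Tuple[float, float]] = {}
    for label, (lo, hi) in DEFAULT_EVENT_BOUNDARIES.items():
        def rescale(p: float) -> float:
            if p <= default_stance:
                return p / default_stance * stance_fraction
            return stance_fraction + (p - default_stance) / (1 - default_stance) * (
                1 - stance_fraction
            )
        out[label] = (rescale(lo), rescale(hi))
    # force exact endpoints against float drift
    out["A"] = (0.0, out["A"][1])
    out["G"] = (out["G"][0], 1.0)
    return out
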