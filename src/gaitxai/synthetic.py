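"""Synthetic gait generator.

Emulates the two recording scenarios the analysis pipeline consumes:

* ``pd`` -- insole force-sensor walks: 19 raw text columns (timestamp,
  8 heel-to-toe sensors per foot, 2 per-foot sums) at 100 frames/s,
  windowed to 500 x 18 samples, four severity classes (healthy control 0
  and Hoehn-Yahr stages 2, 2.5, 3).
* ``cognitive`` -- optical-fiber floor-sensor walks: 116 channels in three
  plies (22/47/47) at 20 frames/s, 100-frame windows, 21 subjects x
  5 walking manners (normal M1 plus four dual tasks M2-M5) x 10 trials.

The generator plants class-discriminative signal at named gait-cycle
events: each non-reference class modifies the whole-frame force (a
tremor-like oscillation, optionally combined with attenuation) while the
reference foot's phase traverses one target event interval. The frames so
modified are returned as ground-truth event windows, which makes
classification, relevance propagation, perturbation analysis and event
assignment all testable end to end without any real recordings.

Every stochastic draw flows from a counter-based stream split
(`numpy` ``SeedSequence`` spawn keys) so per-subject/trial streams are
independent of generation order and the output is bit-reproducible for a
fixed (config, seed).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import GaitDataset, RawRecording
from .phase import EVENT_LABELS, GaitPhaseModel

__all__ = [
    "WaveformParams",
    "ClassEffect",
    "GeneratorConfig",
    "grf_waveform",
    "render_channels",
    "generate_pd_recording",
    "generate_pd_dataset",
    "generate_cognitive_dataset",
    "write_gaitpdb",
    "write_config_json",
    "PD_CLASSES",
    "PD_DEFAULT_EFFECTS",
    "COGNITIVE_CLASSES",
    "COGNITIVE_DEFAULT_EFFECTS",
]

PD_CLASSES = [0, 2, 2.5, 3]
COGNITIVE_CLASSES = ["M1", "M2", "M3", "M4", "M5"]

#: Channel counts of the three optical-fiber plies (lengthwise, +60deg,
#: -60deg diagonal).
COGNITIVE_PLY_SIZES = (22, 47, 47)


@dataclass(frozen=True)
class WaveformParams:
    """Shape of the double-bump (M-shaped) vertical GRF stance profile.

    The profile is a piecewise raised-cosine interpolation through knots at
    stance progress 0, 0.25, 0.5, 0.75, 1 with values 0, ``peak1``,
    ``valley``, ``peak2``, 0, so the two local maxima sit exactly at 25%
    and 75% of stance and the curve meets the zero-force swing phase
    continuously (and with zero slope) at heel strike and toe-off.
    """

    peak1: float = 1.0
    peak2: float = 0.95
    valley: float = 0.65


@dataclass(frozen=True)
class ClassEffect:
    """A localized class-discriminative modification of the gait signal.

    While the reference foot's phase lies inside ``target_event``'s
    interval, all channels are scaled by ``amplitude_scale`` and modulated
    by a tremor-like oscillation of relative amplitude
    ``tremor_amplitude`` at ``tremor_hz`` (with a short taper so the
    modification stays inside the interval). The attenuation emulates the
    weakened ground reaction force of the affected phase; the oscillation
    emulates its impaired force smoothness and gives the class an *active*
    signature that relevance propagation can attribute to the event
    (pure absence of force is not attributable to the silent frames).
    ``timing_jitter_sd`` (seconds) jitters the interval position per
    cycle. The reference class of each scenario carries no effect.
    """

    target_event: str
    amplitude_scale: float
    timing_jitter_sd: float = 0.01
    applies_to: object = None
    tremor_amplitude: float = 0.35
    tremor_hz: float = 6.0

    def __post_init__(self) -> None:
        if self.target_event not in EVENT_LABELS:
            raise ValueError(f"unknown target event {self.target_event!r}")
        if not self.amplitude_scale > 0:
            raise ValueError("amplitude_scale must be > 0")
        if not 0 <= self.tremor_amplitude < 1:
            raise ValueError("tremor_amplitude must lie in [0, 1)")


#: Severity -> event markers: stage 2 at mid-stance C, stage 2.5 at loading
#: response B, stage 3 at terminal swing G; healthy 0 is the untouched
#: reference. The default signatures are pure force-smoothness tremors
#: (amplitude preserved); the narrow low-force loading-response event
#: carries the strongest, fastest oscillation so its signature survives
#: spatial averaging.
PD_DEFAULT_EFFECTS = [
    ClassEffect("C", 1.0, 0.01, 2, tremor_amplitude=0.5, tremor_hz=15.0),
    ClassEffect("B", 1.0, 0.01, 2.5, tremor_amplitude=0.95, tremor_hz=25.0),
    ClassEffect("G", 1.0, 0.01, 3, tremor_amplitude=0.7, tremor_hz=15.0),
]

#: Dual-task -> event markers: listening M2 at heel strike A, serial-7s M3
#: at toe-off F, texting M4 at terminal swing G, talking M5 at pre-swing
#: double support E; normal M1 is the untouched reference. Tremor
#: frequencies sit below the 10 Hz Nyquist limit of the 20 frames/s
#: floor sensor.
COGNITIVE_DEFAULT_EFFECTS = [
    ClassEffect("A", 1.0, 0.02, "M2", tremor_amplitude=0.8, tremor_hz=8.0),
    ClassEffect("F", 1.0, 0.02, "M3", tremor_amplitude=0.6, tremor_hz=6.0),
    ClassEffect("G", 1.0, 0.02, "M4", tremor_amplitude=0.7, tremor_hz=7.0),
    ClassEffect("E", 1.0, 0.02, "M5", tremor_amplitude=0.6, tremor_hz=9.0),
]


@dataclass
class GeneratorConfig:
    """Study-condition parameters of one synthetic scenario."""

    scenario: str = "pd"
    n_subjects: int = 10
    trials_per_subject_per_class: int = 2
    sample_rate: float = 100.0
    window_len: int = 500
    n_channels: int = 19
    subject_weight_scale_range: Tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 0.02
    #: event intervals narrower than this fraction of a cycle are dilated
    #: symmetrically before the effect is applied (needed at 20 Hz, where
    #: the 2%-wide heel-strike interval would otherwise cover < 1 frame)
    min_effect_width: float = 0.0
    #: relative sd of per-subject modulation of effect strength/timing
    subject_signature_sd: float = 0.0
    #: relative sd of the per-subject mean cycle duration
    subject_cadence_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("pd", "cognitive"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "pd" and self.n_channels not in (18, 19):
            raise ValueError("pd scenario uses 19 raw columns (18 processed)")
        if self.scenario == "cognitive" and self.n_channels != 116:
            raise ValueError("cognitive scenario uses 116 channels")
        lo, hi = self.subject_weight_scale_range
        if not 0 < lo <= hi:
            raise ValueError("subject_weight_scale_range must be a positive interval")

    @property
    def classes(self) -> List:
        return list(PD_CLASSES) if self.scenario == "pd" else list(COGNITIVE_CLASSES)

    @classmethod
    def pd(cls, **kw) -> "GeneratorConfig":
        kw.setdefault("scenario", "pd")
        kw.setdefault("sample_rate", 100.0)
        kw.setdefault("window_len", 500)
        kw.setdefault("n_channels", 19)
        return cls(**kw)

    @classmethod
    def cognitive(cls, **kw) -> "GeneratorConfig":
        kw.setdefault("scenario", "cognitive")
        kw.setdefault("n_subjects", 21)
        kw.setdefault("trials_per_subject_per_class", 10)
        kw.setdefault("sample_rate", 20.0)
        kw.setdefault("window_len", 100)
        kw.setdefault("n_channels", 116)
        kw.setdefault("min_effect_width", 0.10)
        kw.setdefault("subject_signature_sd", 0.15)
        return cls(**kw)


# ---------------------------------------------------------------------------
# deterministic stream splitting

_PURPOSE = {"cadence": 1, "weight": 2, "noise": 3, "timing": 4, "signature": 5, "start": 6}


def _stream(seed: int, *keys: int) -> np.random.Generator:
    """Counter-based substream: independent of draw order elsewhere."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(keys)))


# ---------------------------------------------------------------------------
# waveform

def grf_waveform(
    phase,
    phase_model: Optional[GaitPhaseModel] = None,
    params: Optional[WaveformParams] = None,
):
    """Vertical ground-reaction force at gait phase(s) in [0, 1).

    Returns the smooth double-bump stance profile inside the stance
    interval and exactly 0 over swing; continuous at both stance
    boundaries. Accepts scalars or arrays.
    """
    phase_model = phase_model or GaitPhaseModel()
    params = params or WaveformParams()
    p = np.asarray(phase, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("phase must lie in [0, 1)")
    s = p / phase_model.stance_fraction  # stance progress
    knots_x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    knots_y = np.array([0.0, params.peak1, params.valley, params.peak2, 0.0])
    seg = np.clip(np.searchsorted(knots_x, s, side="right") - 1, 0, 3)
    x0, x1 = knots_x[seg], knots_x[seg + 1]
    y0, y1 = knots_y[seg], knots_y[seg + 1]
    t = (s - x0) / (x1 - x0)
    vals = y0 + (y1 - y0) * 0.5 * (1 - np.cos(np.pi * t))
    # the loading ramp rises with nonzero slope (impact-like onset), while
    # every other transition stays cosine-smooth with flat knots
    vals = np.where(seg == 0, knots_y[1] * np.sin(0.5 * np.pi * t), vals)
    out = np.where(s < 1.0, vals, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# phase simulation

def _simulate_reference_phase(
    n_frames: int,
    sample_rate: float,
    phase_model: GaitPhaseModel,
    rng: np.random.Generator,
    start_phase: float = 0.0,
    cycle_duration: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference-foot phase per frame with per-cycle cadence jitter.

    Returns (phase[t] in [0,1), cycle_index[t], heel_strike_frames).
    """
    cd = phase_model.cycle_duration if cycle_duration is None else cycle_duration
    total_t = n_frames / sample_rate
    n_cycles = int(np.ceil(total_t / cd)) + 4
    durations = cd * (
        1.0 + phase_model.cadence_jitter_sd * rng.standard_normal(n_cycles)
    )
    durations = np.clip(durations, 0.4 * cd, 2.0 * cd)
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    starts -= start_phase * durations[0]  # phase at t=0 equals start_phase
    t = np.arange(n_frames) / sample_rate
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_cycles - 1)
    phase = (t - starts[idx]) / durations[idx]
    phase = np.clip(phase, 0.0, np.nextafter(1.0, 0.0))
    strike_times = starts[(starts > 0) & (starts < total_t)]
    strike_frames = np.round(strike_times * sample_rate).astype(int)
    strike_frames = strike_frames[strike_frames < n_frames]
    return phase, idx, strike_frames


def _effect_scale(
    phase: np.ndarray,
    cycle_idx: np.ndarray,
    effect: ClassEffect,
    phase_model: GaitPhaseModel,
    rng: np.random.Generator,
    min_width: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frame multiplicative scale and the ground-truth effect mask."""
    lo, hi = phase_model.event_interval(effect.target_event)
    if hi - lo < min_width:
        pad = (min_width - (hi - lo)) / 2
        lo, hi = lo - pad, hi + pad
    width = hi - lo
    amp = effect.amplitude_scale
    jitter_sd_phase = effect.timing_jitter_sd / phase_model.cycle_duration
    n_cycles = int(cycle_idx.max()) + 1
    shifts = jitter_sd_phase * rng.standard_normal(n_cycles)
    shifted = np.mod(phase - shifts[cycle_idx] - lo, 1.0)
    u = shifted / width  # in [0,1) inside the (jittered) interval
    inside = u < 1.0
    margin = 0.10
    taper = np.clip(np.minimum(u / margin, (1.0 - u) / margin), 0.0, 1.0)
    weight = np.where(inside, taper, 0.0)
    scale = 1.0 - (1.0 - amp) * weight
    # ground truth = exactly the frames actually modified
    mask = inside & (weight > 0)
    return scale, mask, weight


# ---------------------------------------------------------------------------
# channel rendering

def _pd_sensor_weights(phase: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Heel-to-toe activation of the 8 insole sensors through stance.

    Gaussian activation windows whose centers advance linearly from heel
    (sensor 1) to toe (sensor 8) as stance progresses; zero in swing.
    Shape (T, 8).
    """
    s = phase / stance_fraction
    centers = (np.arange(8) + 0.5) / 8.0
    g = np.exp(-0.5 * ((s[:, None] - centers[None, :]) / 0.18) ** 2)
    return np.where((s < 1.0)[:, None], g, 0.0)


def render_channels(
    forces: np.ndarray,
    phases: np.ndarray,
    config: GeneratorConfig,
    phase_model: Optional[GaitPhaseModel] = None,
    seed: int = 0,
    weight: float = 1.0,
    channel_gains: Optional[np.ndarray] = None,
) -> RawRecording:
    """Distribute per-foot forces over the scenario's sensor channels.

    Parameters
    ----------
    forces : (T, 2) per-frame force of (left, right) foot
    phases : (T, 2) per-frame gait phase of (left, right) foot
    config : GeneratorConfig (scenario decides the channel layout)
    seed : stream seed for sensor noise
    weight : per-subject amplitude factor (body-weight surrogate)
    channel_gains : optional per-channel multiplicative gains (cognitive
        subject signature)

    For the pd scenario the output is the 19-column gaitpdb dialect
    (timestamp, L1..L8, R1..R8, Lsum, Rsum) with the sum columns equal to
    the sum of that foot's 8 sensors at every frame, and all force columns
    non-negative. For the cognitive scenario, 116 channels in three plies.
    """
    phase_model = phase_model or GaitPhaseModel()
    forces = np.asarray(forces, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if forces.shape != phases.shape or forces.ndim != 2 or forces.shape[1] != 2:
        raise ValueError("forces and phases must both have shape (T, 2)")
    T = forces.shape[0]
    rng = _stream(seed, _PURPOSE["noise"])
    if config.scenario == "pd":
        left = forces[:, 0:1] * _pd_sensor_weights(phases[:, 0], phase_model.stance_fraction)
        right = forces[:, 1:2] * _pd_sensor_weights(phases[:, 1], phase_model.stance_fraction)
        sensors = np.concatenate([left, right], axis=1) * weight
        if config.noise_sd > 0:
            sensors = sensors + rng.normal(0.0, config.noise_sd * weight, sensors.shape)
        sensors = np.maximum(sensors, 0.0)
        lsum = sensors[:, :8].sum(axis=1, keepdims=True)
        rsum = sensors[:, 8:].sum(axis=1, keepdims=True)
        ts = (np.arange(T) / config.sample_rate)[:, None]
        values = np.concatenate([ts, sensors, lsum, rsum], axis=1)
        return RawRecording("gaitpdb-19col", values, config.sample_rate, has_timestamp=True)
    # cognitive: three plies of POF channels, each a smoothed projection of
    # the two-foot force field
    chans = []
    for ply, size in enumerate(COGNITIVE_PLY_SIZES):
        pos = np.linspace(0.0, 1.0, size)
        w_left = 0.05 + np.exp(-0.5 * ((pos - 0.38) / 0.18) ** 2)
        w_right = 0.05 + np.exp(-0.5 * ((pos - 0.62) / 0.18) ** 2)
        k = 1 if ply == 0 else 3  # diagonal plies integrate a longer path
        kern = np.ones(k) / k
        f_l = np.convolve(forces[:, 0], kern, mode="same")
        f_r = np.convolve(forces[:, 1], kern, mode="same")
        chans.append(f_l[:, None] * w_left[None, :] + f_r[:, None] * w_right[None, :])
    values = np.concatenate(chans, axis=1) * weight
    if channel_gains is not None:
        values = values * np.asarray(channel_gains, dtype=float)[None, :]
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd * weight, values.shape)
    return RawRecording("pof-116col", values, config.sample_rate, has_timestamp=False)


# ---------------------------------------------------------------------------
# dataset generation

def _check_effects(effects: Sequence[ClassEffect], required_classes: Sequence) -> Dict:
    by_class = {}
    for e in effects:
        if e.applies_to in by_class:
            raise ValueError(f"duplicate ClassEffect for class {e.applies_to!r}")
        by_class[e.applies_to] = e
    missing = [c for c in required_classes if c not in by_class]
    if missing:
        raise ValueError(f"effects must cover classes {list(required_classes)}; missing {missing}")
    return by_class


def _simulate_window(
    config: GeneratorConfig,
    phase_model: GaitPhaseModel,
    params: WaveformParams,
    effect: Optional[ClassEffect],
    seed: int,
    keys: Tuple[int, ...],
    weight: float,
    cycle_duration: float,
    channel_gains: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One window: (values without timestamp, effect mask, strike frames)."""
    T = config.window_len
    rng_cad = _stream(seed, *keys, _PURPOSE["cadence"])
    start_phase = _stream(seed, *keys, _PURPOSE["start"]).uniform(0.0, 1.0)
    phase_l, cyc, strikes = _simulate_reference_phase(
        T, config.sample_rate, phase_model, rng_cad, start_phase, cycle_duration
    )
    phase_r = np.mod(phase_l + phase_model.foot_phase_offset, 1.0)
    f_l = grf_waveform(phase_l, phase_model, params)
    f_r = grf_waveform(phase_r, phase_model, params)
    if effect is not None:
        rng_tim = _stream(seed, *keys, _PURPOSE["timing"])
        scale, mask, envelope = _effect_scale(
            phase_l, cyc, effect, phase_model, rng_tim, config.min_effect_width,
        )
        if effect.tremor_amplitude > 0:
            t_sec = np.arange(T) / config.sample_rate
            tremor_phase = rng_tim.uniform(0.0, 2 * np.pi)
            osc = np.sin(2 * np.pi * effect.tremor_hz * t_sec + tremor_phase)
            scale = scale * (1.0 + effect.tremor_amplitude * envelope * osc)
        f_l = f_l * scale
        f_r = f_r * scale
    else:
        mask = np.zeros(T, dtype=bool)
    forces = np.stack([f_l, f_r], axis=1)
    phases = np.stack([phase_l, phase_r], axis=1)
    rec = render_channels(
        forces, phases, config, phase_model,
        seed=_stream(seed, *keys).integers(0, 2**31 - 1),
        weight=weight, channel_gains=channel_gains,
    )
    if config.scenario == "cognitive" and mask.any():
        # the diagonal plies smooth over 3 frames, smearing the effect one
        # frame beyond the phase interval; the ground-truth mask covers
        # every frame actually touched
        mask = np.convolve(mask.astype(float), np.ones(3), mode="same") > 0
    values = rec.values[:, 1:] if rec.has_timestamp else rec.values
    return values, mask, strikes


def _subject_weight(config: GeneratorConfig, seed: int, subj_key: int) -> float:
    lo, hi = config.subject_weight_scale_range
    u = _stream(seed, subj_key, _PURPOSE["weight"]).uniform(0.0, 1.0)
    return float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))


def generate_pd_dataset(
    config: Optional[GeneratorConfig] = None,
    effects: Optional[Sequence[ClassEffect]] = None,
    seed: Optional[int] = None,
    phase_model: Optional[GaitPhaseModel] = None,
    params: Optional[WaveformParams] = None,
) -> GaitDataset:
    """Balanced 4-class severity dataset of 500 x 18 windows.

    Each non-healthy class attenuates the signal at its marker event
    (defaults: stage 2 at C, 2.5 at B, 3 at G); the healthy class 0 is the
    unmodified reference. Subjects are disjoint across classes (one
    severity per patient). The returned dataset carries the per-window
    ground-truth effect masks and the planted class->event map.
    """
    config = config or GeneratorConfig.pd()
    if config.scenario != "pd":
        raise ValueError("generate_pd_dataset requires a pd-scenario config")
    effects = list(effects) if effects is not None else list(PD_DEFAULT_EFFECTS)
    phase_model = phase_model or GaitPhaseModel()
    params = params or WaveformParams()
    for e in effects:
        phase_model.event_interval(e.target_event)  # raises on unknown event
    by_class = _check_effects(effects, [c for c in PD_CLASSES if c != 0])
    seed = config.seed if seed is None else int(seed)

    n_ch = 18
    values, masks, labels, subjects, strikes = [], [], [], [], []
    for ci, cls in enumerate(PD_CLASSES):
        effect = by_class.get(cls)
        for s in range(config.n_subjects):
            subj_key = ci * 10_000 + s
            weight = _subject_weight(config, seed, subj_key)
            cd = phase_model.cycle_duration * float(
                1.0
                + config.subject_cadence_sd
                * _stream(seed, subj_key, _PURPOSE["cadence"]).standard_normal()
            )
            for trial in range(config.trials_per_subject_per_class):
                v, m, hs = _simulate_window(
                    config, phase_model, params, effect, seed,
                    (ci, s, trial), weight, cd,
                )
                values.append(v)
                masks.append(m)
                strikes.append(hs)
                labels.append(cls)
                subjects.append(f"pd_c{ci}_s{s:02d}")
    planted = {str(e.applies_to): e.target_event for e in effects}
    ds = GaitDataset(
        np.stack(values),
        labels=labels,
        subject_ids=subjects,
        classes=PD_CLASSES,
        dataset_tag="synthetic",
        sample_rate=config.sample_rate,
        event_windows=np.stack(masks),
        planted_events=planted,
        strike_frames=strikes,
    )
    assert ds.values.shape[1:] == (config.window_len, n_ch)
    return ds


def generate_cognitive_dataset(
    config: Optional[GeneratorConfig] = None,
    effects: Optional[Sequence[ClassEffect]] = None,
    seed: Optional[int] = None,
    phase_model: Optional[GaitPhaseModel] = None,
    params: Optional[WaveformParams] = None,
) -> GaitDataset:
    """Within-subject 5-class dual-task dataset of 100 x 116 windows.

    Default geometry matches the study conditions: 21 subjects x 5 walking
    manners x 10 trials = 1050 samples. M1 (normal gait) is the unmodified
    reference; M2-M5 carry subject-modulated effects at their marker
    events. The per-subject dual-task signature is a subject-specific
    modulation of effect strength plus a subject-specific channel-gain
    pattern.
    """
    config = config or GeneratorConfig.cognitive()
    if config.scenario != "cognitive":
        raise ValueError("generate_cognitive_dataset requires a cognitive-scenario config")
    effects = list(effects) if effects is not None else list(COGNITIVE_DEFAULT_EFFECTS)
    # a ~1.1 s cycle puts 4-5 cycles into one 5 s window
    phase_model = phase_model or GaitPhaseModel(cycle_duration=1.1)
    params = params or WaveformParams()
    for e in effects:
        phase_model.event_interval(e.target_event)
    by_class = _check_effects(effects, COGNITIVE_CLASSES[1:])
    seed = config.seed if seed is None else int(seed)

    values, masks, labels, subjects, strikes = [], [], [], [], []
    for s in range(config.n_subjects):
        weight = _subject_weight(config, seed, s)
        rng_sig = _stream(seed, s, _PURPOSE["signature"])
        gains = 1.0 + 0.08 * rng_sig.standard_normal(config.n_channels)
        gains = np.clip(gains, 0.5, 1.5)
        cd = phase_model.cycle_duration * float(
            1.0 + config.subject_cadence_sd * rng_sig.standard_normal()
        )
        sig_mod = 1.0 + config.subject_signature_sd * rng_sig.standard_normal(
            len(COGNITIVE_CLASSES)
        )
        for ci, cls in enumerate(COGNITIVE_CLASSES):
            effect = by_class.get(cls)
            if effect is not None:
                # each subject expresses the dual-task signature with its
                # own strength (and, through the shared streams, timing)
                effect = replace(
                    effect,
                    tremor_amplitude=float(
                        np.clip(effect.tremor_amplitude * sig_mod[ci], 0.0, 0.95)
                    ),
                )
            for trial in range(config.trials_per_subject_per_class):
                v, m, hs = _simulate_window(
                    config, phase_model, params, effect, seed,
                    (100 + ci, s, trial), weight, cd,
                    channel_gains=gains,
                )
                values.append(v)
                masks.append(m)
                strikes.append(hs)
                labels.append(cls)
                subjects.append(f"cog_s{s:02d}")
    planted = {str(e.applies_to): e.target_event for e in effects}
    return GaitDataset(
        np.stack(values),
        labels=labels,
        subject_ids=subjects,
        classes=COGNITIVE_CLASSES,
        dataset_tag="cognitive",
        sample_rate=config.sample_rate,
        event_windows=np.stack(masks),
        planted_events=planted,
        strike_frames=strikes,
    )


def generate_pd_recording(
    n_frames: int,
    config: Optional[GeneratorConfig] = None,
    seed: int = 0,
    phase_model: Optional[GaitPhaseModel] = None,
    source_id: str = "synthetic",
) -> RawRecording:
    """One variable-length healthy 19-column recording (for I/O fixtures)."""
    config = config or GeneratorConfig.pd()
    phase_model = phase_model or GaitPhaseModel()
    params = WaveformParams()
    rng_cad = _stream(seed, 0, _PURPOSE["cadence"])
    phase_l, _, _ = _simulate_reference_phase(
        n_frames, config.sample_rate, phase_model, rng_cad
    )
    phase_r = np.mod(phase_l + phase_model.foot_phase_offset, 1.0)
    forces = np.stack(
        [grf_waveform(phase_l, phase_model, params), grf_waveform(phase_r, phase_model, params)],
        axis=1,
    )
    phases = np.stack([phase_l, phase_r], axis=1)
    rec = render_channels(forces, phases, config, phase_model, seed=seed)
    rec.source_id = source_id
    return rec


# ---------------------------------------------------------------------------
# writers

def write_gaitpdb(recording: RawRecording, path: str) -> None:
    """Write a 19-column recording as whitespace-delimited text.

    Values are printed with 17 significant digits so the write->read round
    trip is bit-exact.
    """
    if recording.dialect != "gaitpdb-19col":
        raise ValueError("write_gaitpdb only writes the gaitpdb-19col dialect")
    np.savetxt(path, recording.values, fmt="%.17g", delimiter="\t")


def write_config_json(config: GeneratorConfig, path: str) -> None:
    """Provenance sidecar for a generated dataset."""
    with open(path, "w") as f:
        json.dump(asdict(config), f, indent=2, default=str)
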