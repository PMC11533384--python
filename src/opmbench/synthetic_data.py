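"""Paradigm schedules, source timecourses, background fields, and fully
assembled raw recordings.

This module defines the study conditions every analysis in the package is
validated against:

* the visuo-motor paradigm (60 circles / 120 faces / 25 catch trials with
  1.25 ± 0.2 s jittered rests, 396 s expected total);
* the phantom amplitude sweep (17 Hz drive, 2 s on / 1 s off, nine drive
  amplitudes 0.01–1 mA repeated eight times);
* the phantom background sweep (1 mA drive, five repeats at each of 81
  background levels 0–8 nT in 0.1 nT steps: 405 on-epochs);
* the sit-to-stand task (8 s trials, alternating cues, a 2.5 nT
  movement-locked background excursion on top of a ~3 nT ambient field);
* the cross-site motor-block task (3 s move / 3 s rest, 50 trials/run).

Sources are current dipoles with role-specific statistics: band-limited
beta (13–30 Hz) activity with event-related desynchronisation, narrowband
visual gamma (52–65 Hz) with stimulus-locked amplitude increase, a
deterministic evoked response peaking 170 ms after face onsets, and 1/f
brain noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .array_geometry import SensorArray, orientation_matrix
from .forward_models import (
    Dipole,
    TriangleCoil,
    dipole_field_sphere,
    default_phantom_coil,
    triangle_coil_field,
)
from .opm_sensor import (
    NT,
    SensorState,
    add_sensor_noise,
    closed_loop_response,
    open_loop_response,
)

__all__ = [
    "Event",
    "ParadigmSchedule",
    "SourceSpec",
    "SourceScenario",
    "RawRecording",
    "TRIGGER_CODES",
    "make_visuomotor_schedule",
    "make_phantom_amplitude_sweep",
    "make_phantom_background_sweep",
    "make_sit_stand_schedule",
    "make_motor_block_schedule",
    "simulate_source_timecourses",
    "background_timecourse",
    "assemble_recording",
]

#: integer trigger code per event type (stable; recorded in the container)
TRIGGER_CODES = {
    "circles": 1,
    "faces": 2,
    "catch": 3,
    "cue_up": 4,
    "cue_down": 5,
    "move": 6,
    "rest": 7,
    "phantom_on": 8,
}

PHANTOM_FREQ = 17.0  # Hz
PHANTOM_ON = 2.0  # s
PHANTOM_OFF = 1.0  # s
AMPLITUDE_SWEEP_MA = (0.01, 0.02, 0.05, 0.08, 0.1, 0.2, 0.5, 0.8, 1.0)


@dataclass(frozen=True)
class Event:
    onset: float  # seconds
    type: str
    duration: float  # seconds
    value: float = 0.0  # drive amplitude (mA) or other scalar payload
    background: float = float("nan")  # applied background level, nT (phantom sweep)


@dataclass(frozen=True)
class ParadigmSchedule:
    events: tuple[Event, ...]
    total_duration: float
    seed: int = 0

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def of_type(self, event_type: str) -> list[Event]:
        return [e for e in self.events if e.type == event_type]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.type] = out.get(e.type, 0) + 1
        return out


@dataclass(frozen=True)
class SourceSpec:
    """One dipole plus the statistics of its moment timecourse."""

    dipole: Dipole
    role: str  # beta_motor | gamma_visual | evoked_fusiform | brain_noise
    band: tuple[float, float] = (13.0, 30.0)
    amplitude: float = 5e-9  # baseline RMS moment, A·m (5 nAm)
    modulation_depth: float = 0.5  # fractional envelope change
    latency: float = 0.170  # s, evoked peak latency


@dataclass(frozen=True)
class SourceScenario:
    sources: tuple[SourceSpec, ...] = ()

    def __post_init__(self):
        for s in self.sources:
            if not 0.0 <= s.modulation_depth <= 1.0:
                raise ValueError("modulation depth must lie in [0, 1]")
            if not (1.0 <= s.band[0] < s.band[1] <= 150.0):
                raise ValueError("band must lie within 1–150 Hz")


@dataclass
class RawRecording:
    """Channels × samples field data with triggers and provenance."""

    data: np.ndarray  # (n_channels, n_samples), tesla
    fs: float
    triggers: np.ndarray  # structured: sample, code; plus labels list
    trigger_labels: list[str]
    array: SensorArray
    sensor_state: SensorState
    provenance: dict = field(default_factory=dict)
    saturated: np.ndarray | None = None  # per (sensor, axis) closed-loop flag

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# -- schedules ---------------------------------------------------------------


def make_visuomotor_schedule(seed: int = 0) -> ParadigmSchedule:
    """60 circles (1.0 s) + 120 faces (0.5 s) + 25 catch (0.8 s) trials,
    pseudo-randomised, each followed by a rest drawn uniformly from
    1.25 ± 0.2 s.  Expected duration with the jitter at its mean is
    396.25 s (396 s truncated to whole seconds)."""
    rng = np.random.default_rng(seed)
    trials = ["circles"] * 60 + ["faces"] * 120 + ["catch"] * 25
    rng.shuffle(trials)
    stim = {"circles": 1.0, "faces": 0.5, "catch": 0.8}
    events, t = [], 0.0
    for kind in trials:
        events.append(Event(onset=t, type=kind, duration=stim[kind]))
        t += stim[kind] + rng.uniform(1.05, 1.45)
    return ParadigmSchedule(events=tuple(events), total_duration=t, seed=seed)


def _phantom_epochs(amplitudes_ma, backgrounds_nt) -> ParadigmSchedule:
    events, t = [], 0.0
    for amp, bg in zip(amplitudes_ma, backgrounds_nt):
        events.append(
            Event(onset=t, type="phantom_on", duration=PHANTOM_ON, value=amp, background=bg)
        )
        t += PHANTOM_ON + PHANTOM_OFF
    return ParadigmSchedule(events=tuple(events), total_duration=t)


def make_phantom_amplitude_sweep() -> ParadigmSchedule:
    """Nine drive amplitudes (0.01–1 mA, listed order) cycled eight times;
    each epoch is 2 s of 17 Hz drive followed by 1 s off (72 epochs,
    216 s).  Background field is zero throughout."""
    amps = list(AMPLITUDE_SWEEP_MA) * 8
    return _phantom_epochs(amps, [0.0] * len(amps))


def make_phantom_background_sweep() -> ParadigmSchedule:
    """1 mA drive, five epochs at each background level 0.0, 0.1, …, 8.0 nT
    (81 levels, stepped upward): 405 on-epochs, 1215 s."""
    levels = np.round(np.arange(81) * 0.1, 10)
    amps, bgs = [], []
    for lvl in levels:
        amps.extend([1.0] * 5)
        bgs.extend([float(lvl)] * 5)
    return _phantom_epochs(amps, bgs)


def make_sit_stand_schedule(
    n_trials: int = 20,
    seed: int = 0,
    trial_duration: float = 8.0,
    ramp_magnitude: float = 2.5,
    ramp_duration: float = 2.0,
    ambient: float = 3.0,
) -> ParadigmSchedule:
    """Alternating sit-to-stand / stand-to-sit trials.

    Each 8 s trial starts with a 1 s auditory cue (``cue_up`` = 1400 Hz
    stand cue, ``cue_down`` = 1000 Hz sit cue, strictly alternating).  The
    head translates through the static shielded-room field while moving, so
    the background rises (stand) or falls (sit) by ``ramp_magnitude`` nT
    with a raised-cosine profile over the first ``ramp_duration`` seconds,
    on top of a constant ``ambient`` nT vertical field (the room is neither
    degaussed nor actively nulled in this paradigm).  ``Event.value`` holds
    the background level at the *end* of the trial; ``Event.background``
    the level at its start.  The motor (beta) source desynchronises during
    the first 4 s of every trial.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even (trials alternate)")
    events = []
    level = ambient
    for k in range(n_trials):
        kind = "cue_up" if k % 2 == 0 else "cue_down"
        target = ambient + ramp_magnitude if k % 2 == 0 else ambient
        events.append(
            Event(onset=k * trial_duration, type=kind, duration=1.0,
                  value=target, background=level)
        )
        level = target
    return ParadigmSchedule(
        events=tuple(events), total_duration=n_trials * trial_duration, seed=seed
    )


def make_motor_block_schedule(n_trials: int = 50) -> ParadigmSchedule:
    """n_trials of (3 s move, 3 s rest); cross-site default 50 per run."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    events = []
    for k in range(n_trials):
        events.append(Event(onset=6.0 * k, type="move", duration=3.0))
        events.append(Event(onset=6.0 * k + 3.0, type="rest", duration=3.0))
    return ParadigmSchedule(events=tuple(events), total_duration=6.0 * n_trials)


# -- source timecourses ------------------------------------------------------

#: movement window (seconds after event onset) per movement-type event
_MOVEMENT_WINDOWS = {
    "catch": (-0.3, 0.6),
    "move": (0.0, 3.0),
    "cue_up": (0.0, 4.0),
    "cue_down": (0.0, 4.0),
}

_EDGE = 0.1  # s, raised-cosine edge applied to envelope transitions


def _smooth_gate(t: np.ndarray, windows: list[tuple[float, float]]) -> np.ndarray:
    """0/1 gate over the listed windows with raised-cosine edges."""
    gate = np.zeros_like(t)
    for a, b in windows:
        rise = np.clip((t - a) / _EDGE, 0.0, 1.0)
        fall = np.clip((b - t) / _EDGE, 0.0, 1.0)
        gate = np.maximum(gate, 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall)))
    return gate


def _band_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (4th-order
    Butterworth, zero phase)."""
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def _pink_noise(n: int, fs: float, rng, f_floor: float = 1.0) -> np.ndarray:
    """Unit-RMS noise with 1/f amplitude spectrum above ``f_floor``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.maximum(f, f_floor)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / np.std(x)


def _evoked_waveform(t: np.ndarray, latency: float) -> np.ndarray:
    """Deterministic biphasic response, unit peak at ``latency`` seconds."""
    w = np.exp(-0.5 * ((t - latency) / 0.020) ** 2) - 0.45 * np.exp(
        -0.5 * ((t - latency - 0.085) / 0.035) ** 2
    )
    return w


def simulate_source_timecourses(
    schedule: ParadigmSchedule,
    scenario: SourceScenario,
    fs: float,
    seed: int,
) -> dict[int, np.ndarray]:
    """Moment timecourses (A·m) for every source in the scenario.

    Returns a dict keyed by source index into ``scenario.sources``.
    """
    n = int(round(schedule.total_duration * fs))
    t = np.arange(n) / fs
    out: dict[int, np.ndarray] = {}
    for idx, src in enumerate(scenario.sources):
        if fs < 2.0 * src.band[1]:
            raise ValueError(
                f"fs={fs} Hz cannot represent band {src.band} (aliasing)"
            )
        rng = np.random.default_rng([seed, 101, idx])
        if src.role == "beta_motor":
            windows = [
                (e.onset + _MOVEMENT_WINDOWS[e.type][0], e.onset + _MOVEMENT_WINDOWS[e.type][1])
                for e in schedule.events
                if e.type in _MOVEMENT_WINDOWS
            ]
            env = 1.0 - src.modulation_depth * _smooth_gate(t, windows)
            out[idx] = src.amplitude * env * _band_noise(n, fs, src.band, rng)
        elif src.role == "gamma_visual":
            windows = [(e.onset, e.onset + e.duration) for e in schedule.of_type("circles")]
            env = 1.0 + src.modulation_depth * _smooth_gate(t, windows)
            out[idx] = src.amplitude * env * _band_noise(n, fs, src.band, rng)
        elif src.role == "evoked_fusiform":
            tc = np.zeros(n)
            for e in schedule.of_type("faces"):
                tc += _evoked_waveform(t - e.onset, src.latency) * (t >= e.onset)
            out[idx] = src.amplitude * tc
        elif src.role == "brain_noise":
            out[idx] = src.amplitude * _pink_noise(n, fs, rng)
        else:
            raise ValueError(f"unknown source role {src.role!r}")
    return out


# -- background fields -------------------------------------------------------


def background_timecourse(
    schedule: ParadigmSchedule,
    fs: float,
    direction: np.ndarray = (0.0, 0.0, 1.0),
    ramp_duration: float = 2.0,
) -> np.ndarray:
    """(3, n_samples) homogeneous background field, tesla, from the
    per-event background annotations of a schedule.

    Phantom-sweep schedules hold the level constant across each epoch
    (stepped between levels); sit-to-stand schedules ramp from
    ``event.background`` to ``event.value`` with a raised-cosine onset over
    ``ramp_duration`` seconds at each cue.
    """
    n = int(round(schedule.total_duration * fs))
    t = np.arange(n) / fs
    level = np.zeros(n)
    for e in schedule.events:
        if e.type == "phantom_on" and np.isfinite(e.background):
            level[t >= e.onset] = e.background
        elif e.type in ("cue_up", "cue_down"):
            start, target = e.background, e.value
            tau = np.clip((t - e.onset) / ramp_duration, 0.0, 1.0)
            ramp = start + (target - start) * 0.5 * (1.0 - np.cos(np.pi * tau))
            level = np.where(t >= e.onset, ramp, level)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return d[:, None] * (level * NT)[None, :]


def phantom_current(schedule: ParadigmSchedule, fs: float) -> np.ndarray:
    """Coil current timecourse, amperes, from phantom_on events (mA values,
    17 Hz sinusoid during on-epochs, zero otherwise)."""
    n = int(round(schedule.total_duration * fs))
    t = np.arange(n) / fs
    cur = np.zeros(n)
    for e in schedule.of_type("phantom_on"):
        mask = (t >= e.onset) & (t < e.onset + e.duration)
        cur[mask] = e.value * 1e-3 * np.sin(2.0 * np.pi * PHANTOM_FREQ * (t[mask] - e.onset))
    return cur


# -- assembly ----------------------------------------------------------------


def _schedule_triggers(schedule: ParadigmSchedule, fs: float):
    samples = np.array([int(round(e.onset * fs)) for e in schedule.events], dtype=np.int64)
    codes = np.array([TRIGGER_CODES[e.type] for e in schedule.events], dtype=np.int64)
    labels = [e.type for e in schedule.events]
    trig = np.zeros(len(samples), dtype=[("sample", "i8"), ("code", "i8")])
    trig["sample"], trig["code"] = samples, codes
    return trig, labels


def assemble_recording(
    schedule: ParadigmSchedule,
    scenario: SourceScenario,
    array: SensorArray,
    sensor_state: SensorState,
    fs: float,
    seed: int,
    coil: TriangleCoil | None = None,
    background: np.ndarray | None = None,
    sphere_origin: np.ndarray | None = None,
) -> RawRecording:
    """Assemble the full synthetic recording for one experiment.

    Sums dipole fields (spherical-conductor forward model), phantom coil
    fields (if the schedule has phantom epochs), and the homogeneous
    background; projects onto sensor axes; applies the configured sensor
    response (open or closed loop); adds sensor noise; writes triggers.
    Deterministic for a fixed seed.
    """
    n = int(round(schedule.total_duration * fs))
    origin = np.zeros(3) if sphere_origin is None else np.asarray(sphere_origin, dtype=float)
    n_sens = array.n_sensors

    # True vector field at each sensor, sensor-major: (n_sensors, 3(vec), n)
    true_vec = np.zeros((n_sens, 3, n))

    sources = simulate_source_timecourses(schedule, scenario, fs, seed)
    for idx, tc in sources.items():
        src = scenario.sources[idx]
        unit = Dipole(position=src.dipole.position, moment=src.dipole.moment)
        pattern = dipole_field_sphere(unit, array.positions, sphere_origin=origin)
        scale = np.linalg.norm(src.dipole.moment)
        if scale > 0:
            true_vec += pattern[:, :, None] * (tc / scale)[None, None, :]

    has_phantom = any(e.type == "phantom_on" for e in schedule.events)
    if has_phantom:
        coil = coil if coil is not None else default_phantom_coil(array.head_radius + array.standoff)
        pattern = triangle_coil_field(coil, array.positions, current=1.0)
        true_vec += pattern[:, :, None] * phantom_current(schedule, fs)[None, None, :]

    bg_vec = np.zeros((n_sens, 3, n))
    if background is not None:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (3, n):
            raise ValueError(f"background must have shape (3, {n})")
        bg_vec += bg[None, :, :]
        true_vec += bg[None, :, :]

    # project into each sensor's axis frame
    axes = array.axes  # (n_sens, 3(axis), 3(vec))
    field_ax = np.einsum("sav,svn->san", axes, true_vec)
    bg_ax = np.einsum("sav,svn->san", axes, bg_vec)
    del true_vec, bg_vec

    saturated = None
    if sensor_state.mode == "open_loop":
        measured = open_loop_response(field_ax, bg_ax, sensor_state)
    else:
        measured, saturated = closed_loop_response(field_ax, sensor_state, fs)
    del field_ax, bg_ax

    data = measured.reshape(array.n_channels, n)
    data = add_sensor_noise(data, sensor_state, fs, seed=int(seed) + 7919)

    trig, labels = _schedule_triggers(schedule, fs)
    return RawRecording(
        data=data,
        fs=fs,
        triggers=trig,
        trigger_labels=labels,
        array=array,
        sensor_state=sensor_state,
        provenance={
            "seed": int(seed),
            "n_events": len(schedule.events),
            "mode": sensor_state.mode,
            "fs": fs,
        },
        saturated=saturated,
    )
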