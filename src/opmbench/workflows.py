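"""End-to-end experiment runners used by the validation suite and CLI.

These chain the synthetic-data generator, the sensor model, and the
analysis modules into the phantom and sit-to-stand experiments.  The
background sweep is simulated level-by-level (the protocol steps the
field between blocks of epochs, and the loop transient at a step lasts
~5 ms against 2 s epochs), which keeps memory flat without changing the
statistics.
"""

from __future__ import annotations

import numpy as np

from .array_geometry import SensorArray, build_helmet_array, orientation_matrix
from .forward_models import Dipole, SourceGrid, compute_leadfield
from .opm_sensor import SensorState
from .preprocess import apply_filters, apply_hfc, segment
from .presets import ANALYSIS_PRESETS
from .source_recon import compute_covariance, compute_tfs, pseudo_t_image, virtual_electrode
from .synthetic_data import (
    ParadigmSchedule,
    SourceScenario,
    SourceSpec,
    assemble_recording,
    background_timecourse,
    make_phantom_background_sweep,
    make_sit_stand_schedule,
)
from .validation_metrics import ToneAmplitudeSet, background_error_stats, extract_tone_amplitude

__all__ = [
    "run_background_sweep",
    "sweep_error_stats",
    "run_sit_stand",
    "default_motor_dipole",
]

BACKGROUND_DIRECTION = (0.0, 0.0, 1.0)  # vertical in the head frame


def _sub_schedule(events, duration) -> ParadigmSchedule:
    return ParadigmSchedule(events=tuple(events), total_duration=duration)


def run_background_sweep(
    mode: str = "closed_loop",
    seed: int = 0,
    fs: float = 375.0,
    array: SensorArray | None = None,
    state: SensorState | None = None,
    schedule: ParadigmSchedule | None = None,
) -> tuple[ToneAmplitudeSet, np.ndarray]:
    """Simulate the 0–8 nT phantom background sweep and extract per-epoch
    17 Hz amplitudes.

    Returns the :class:`ToneAmplitudeSet` (epochs × channels, tesla) and
    the per-epoch background level in nT.
    """
    array = array if array is not None else build_helmet_array()
    state = (state if state is not None else SensorState()).with_mode(mode)
    schedule = schedule if schedule is not None else make_phantom_background_sweep()
    scenario = SourceScenario()

    levels_all = np.array([e.background for e in schedule.of_type("phantom_on")])
    levels_unique = sorted(set(levels_all))

    amps, levels_out = [], []
    for k, lvl in enumerate(levels_unique):
        evs = [e for e in schedule.of_type("phantom_on") if e.background == lvl]
        t0 = evs[0].onset
        shifted = [
            type(e)(onset=e.onset - t0, type=e.type, duration=e.duration,
                    value=e.value, background=e.background)
            for e in evs
        ]
        block_dur = len(evs) * 3.0
        sub = _sub_schedule(shifted, block_dur)
        bg = background_timecourse(sub, fs, direction=BACKGROUND_DIRECTION)
        rec = assemble_recording(
            sub, scenario, array, state, fs, seed=int(seed) + 104729 * k, background=bg
        )
        ep = segment(rec, (0.0, 2.0), "phantom_on")
        amps.append(extract_tone_amplitude(ep, mode=mode).amplitudes)
        levels_out.extend([lvl] * ep.n_trials)
    return (
        ToneAmplitudeSet(
            amplitudes=np.concatenate(amps, axis=0),
            f0=17.0,
            conditions=np.asarray(levels_out),
            mode=mode,
        ),
        np.asarray(levels_out),
    )


def sweep_error_stats(mode: str = "closed_loop", seed: int = 0, n_top: int = 10, **kw):
    """Mean ± SD percentage amplitude error of the sweep for one mode."""
    amps, levels = run_background_sweep(mode=mode, seed=seed, **kw)
    mean, sd, errs = background_error_stats(amps, levels, n_top=n_top)
    return mean, sd, errs


def default_motor_dipole(amplitude: float = 10e-9) -> SourceSpec:
    """Left sensorimotor beta source (tangential moment, 10 nAm RMS)."""
    pos = np.array([-0.035, 0.0, 0.055])
    r = pos / np.linalg.norm(pos)
    t = np.cross([0.0, 1.0, 0.0], r)
    t /= np.linalg.norm(t)
    return SourceSpec(
        dipole=Dipole(position=pos, moment=amplitude * t),
        role="beta_motor",
        band=(13.0, 30.0),
        amplitude=amplitude,
        modulation_depth=0.5,
    )


def run_sit_stand(
    mode: str = "closed_loop",
    seed: int = 0,
    n_trials: int = 20,
    fs: float = 1500.0,
    grid_spacing: float = 0.004,
    grid_radius: float = 0.075,
    array: SensorArray | None = None,
    source: SourceSpec | None = None,
    ve_location: np.ndarray | None = None,
):
    """Full sit-to-stand pipeline for one sensor mode.

    Simulates the 8-s alternating-trial paradigm with the movement-locked
    background ramp, runs filtering, HFC, segmentation, beta-band
    beamforming (2–3 s vs 6.5–7.5 s contrast), and the virtual-electrode
    TFS at the pseudo-T peak.

    Returns a dict with the recording, pseudo-T image, beta envelope and
    TFS, plus the true source for comparison.
    """
    array = array if array is not None else build_helmet_array()
    source = source if source is not None else default_motor_dipole()
    state = SensorState().with_mode(mode)
    preset = ANALYSIS_PRESETS["sit_stand"]

    schedule = make_sit_stand_schedule(n_trials=n_trials, seed=seed)
    bg = background_timecourse(schedule, fs, direction=BACKGROUND_DIRECTION)
    rec = assemble_recording(
        schedule,
        SourceScenario(sources=(source,)),
        array,
        state,
        fs,
        seed,
        background=bg,
    )

    filtered = apply_filters(rec)
    corrected, proj = apply_hfc(filtered, orientation_matrix(array))

    # beta-band imaging: both cue types are movement trials
    from scipy.signal import butter, sosfiltfilt

    eps = []
    for ev in ("cue_up", "cue_down"):
        eps.append(segment(corrected, preset.window, ev))
    data = np.concatenate([e.data for e in eps], axis=0)
    epochs = eps[0]
    epochs.data = data
    sos = butter(4, preset.band, btype="bandpass", fs=fs, output="sos")
    beta = type(epochs)(
        data=sosfiltfilt(sos, epochs.data, axis=-1),
        window=epochs.window,
        fs=fs,
        event_type="movement",
        channel_ids=epochs.channel_ids,
    )

    grid = SourceGrid.sphere_interior(radius=grid_radius, spacing=grid_spacing)
    lf = compute_leadfield(grid, array)
    cov = compute_covariance(beta, band=preset.band)
    image = pseudo_t_image(
        lf, cov, beta, preset.active, preset.control, projector=proj, polarity=preset.polarity
    )
    peak_loc, _ = image.peak
    if ve_location is not None:
        peak_loc = np.asarray(ve_location, dtype=float)

    # broadband virtual electrode at the peak for the TFS
    broad = type(epochs)(
        data=epochs.data,
        window=epochs.window,
        fs=fs,
        event_type="movement",
        channel_ids=epochs.channel_ids,
    )
    cov_broad = compute_covariance(broad, band=(1.0, 150.0))
    ve = virtual_electrode(peak_loc, lf, cov_broad, broad, projector=proj)
    tfs = compute_tfs(
        ve.timecourses, fs, times=broad.window[0] + np.arange(broad.data.shape[-1]) / fs,
        baseline_window=preset.control,
    )

    # beta-band envelope at the peak (for cross-mode amplitude comparison)
    ve_beta = virtual_electrode(peak_loc, lf, cov, beta, projector=proj)
    from .source_recon import hilbert_envelope

    envelope = hilbert_envelope(ve_beta.timecourses)

    return {
        "recording": rec,
        "image": image,
        "peak": peak_loc,
        "tfs": tfs,
        "envelope": envelope,
        "times": beta.window[0] + np.arange(beta.data.shape[-1]) / fs,
        "source": source,
        "projector": proj,
    }
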