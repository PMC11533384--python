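"""Named experiment and analysis presets.

Each analysis preset bundles the per-trial-type recipe: segmentation
window, frequency band, contrast windows (equal active/control
durations), image kind, and peak polarity (``min`` for beta
desynchronisation contrasts, ``max`` for gamma synchronisation and evoked
responses).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AnalysisPreset:
    event_type: str
    window: tuple[float, float]  # segmentation window, s relative to onset
    band: tuple[float, float]  # Hz
    active: tuple[float, float] | None  # pseudo-T contrast windows
    control: tuple[float, float] | None
    kind: str = "pseudo_T"
    polarity: str = "max"
    t_peak: float | None = None  # pseudo-Z latency, s


ANALYSIS_PRESETS: dict[str, AnalysisPreset] = {
    # visual gamma: circles stimulus, narrowband response
    "circles": AnalysisPreset(
        event_type="circles",
        window=(0.0, 2.0),
        band=(52.0, 65.0),
        active=(0.0, 0.6),
        control=(1.1, 1.7),
        polarity="max",
    ),
    # evoked response to faces, imaged at the ~170 ms peak
    "faces": AnalysisPreset(
        event_type="faces",
        window=(0.0, 1.5),
        band=(2.0, 40.0),
        active=None,
        control=None,
        kind="pseudo_Z",
        polarity="max",
        t_peak=0.170,
    ),
    # beta desynchronisation around the button press
    "catch": AnalysisPreset(
        event_type="catch",
        window=(-0.3, 1.7),
        band=(13.0, 30.0),
        active=(-0.3, 0.3),
        control=(0.8, 1.4),
        polarity="min",
    ),
    # sit-to-stand beta contrast (movement vs late rest)
    "sit_stand": AnalysisPreset(
        event_type="cue_up",
        window=(0.0, 8.0),
        band=(13.0, 30.0),
        active=(2.0, 3.0),
        control=(6.5, 7.5),
        polarity="min",
    ),
    # cross-site motor block
    "motor_block": AnalysisPreset(
        event_type="move",
        window=(0.0, 6.0),
        band=(13.0, 30.0),
        active=(0.5, 1.5),
        control=(3.5, 4.5),
        polarity="min",
    ),
}

#: sampling-rate presets, Hz: integrated-miniaturised system default,
#: rack-mounted system, and the sit-to-stand acquisition
SAMPLING_PRESETS = {"im": 375.0, "rm": 1200.0, "sit_stand": 1500.0}
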