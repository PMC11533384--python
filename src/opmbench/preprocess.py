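"""Quality control, filtering, homogeneous field correction, segmentation.

The automatic QC rules: channels whose mean 60–80 Hz amplitude spectral
density falls outside (7, 30) fT/sqrt(Hz) are removed (too noisy, or dead /
disconnected), and trials whose pooled variance exceeds the mean trial
variance by more than 3 standard deviations are removed in a single pass.
Filtering is 50/100/150 Hz notches plus a 1–150 Hz 4th-order Butterworth
band pass, applied forward-backward (zero phase) so evoked latencies are
preserved.  Homogeneous field correction (HFC) projects out the 3-D
subspace of channel space spanned by spatially uniform fields, using the
channel orientation matrix; the same projector must be applied to lead
fields before beamforming (see :mod:`opmbench.source_recon`).

The pipeline order is fixed: QC -> filters -> HFC -> segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import signal

from .synthetic_data import RawRecording, TRIGGER_CODES

__all__ = [
    "QCReport",
    "Epochs",
    "channel_psd",
    "detect_bad_channels",
    "detect_bad_trials",
    "apply_filters",
    "apply_hfc",
    "segment",
]

FT = 1e-15

#: QC band and thresholds, fT/sqrt(Hz)
QC_BAND = (60.0, 80.0)
QC_HIGH = 30.0
QC_LOW = 7.0


@dataclass
class QCReport:
    """Bad channels/trials with the numeric evidence that flagged them."""

    bad_channels: list[tuple[int, str, float]] = field(default_factory=list)
    bad_trials: list[tuple[int, float, float]] = field(default_factory=list)
    band_noise: np.ndarray | None = None  # per-channel 60–80 Hz ASD, fT/√Hz

    @property
    def bad_channel_ids(self) -> list[int]:
        return sorted({c for c, _, _ in self.bad_channels})

    @property
    def bad_trial_ids(self) -> list[int]:
        return sorted({t for t, _, _ in self.bad_trials})


@dataclass
class Epochs:
    """trials × channels × samples segments around events of one type."""

    data: np.ndarray
    window: tuple[float, float]  # seconds relative to event onset
    fs: float
    event_type: str
    channel_ids: np.ndarray  # original channel indices retained
    dropped_trials: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs

    def drop(self, trial_ids) -> "Epochs":
        keep = [i for i in range(self.n_trials) if i not in set(trial_ids)]
        return dc_replace(
            self,
            data=self.data[keep],
            dropped_trials=self.dropped_trials + sorted(set(trial_ids)),
        )


def channel_psd(
    raw: RawRecording | np.ndarray,
    fs: float | None = None,
    segment_length: float = 2.0,
    overlap: float = 0.5,
):
    """Averaged-periodogram (Welch) amplitude spectral density per channel.

    2-s Hann segments with 50 % overlap by default (0.5 Hz resolution).

    Returns
    -------
    freqs : (n_freqs,) ndarray, Hz
    asd : (n_channels, n_freqs) ndarray, fT/sqrt(Hz)
    """
    if isinstance(raw, RawRecording):
        data, fs = raw.data, raw.fs
    else:
        data = np.atleast_2d(np.asarray(raw, dtype=float))
        if fs is None:
            raise ValueError("fs required for array input")
    nper = int(round(segment_length * fs))
    if data.shape[-1] < nper:
        raise ValueError("recording shorter than one Welch segment")
    freqs, psd = signal.welch(
        data, fs=fs, window="hann", nperseg=nper, noverlap=int(round(overlap * nper)), axis=-1
    )
    return freqs, np.sqrt(psd) / FT


def detect_bad_channels(freqs: np.ndarray, asd: np.ndarray) -> QCReport:
    """Flag channels whose mean 60–80 Hz ASD is > 30 or < 7 fT/sqrt(Hz)."""
    band = (freqs >= QC_BAND[0]) & (freqs <= QC_BAND[1])
    if not np.any(band):
        raise ValueError("spectrum does not cover the 60–80 Hz QC band")
    mean_band = asd[:, band].mean(axis=1)
    report = QCReport(band_noise=mean_band)
    for ch, v in enumerate(mean_band):
        if v > QC_HIGH:
            report.bad_channels.append((ch, "noise_high", float(v)))
        elif v < QC_LOW:
            report.bad_channels.append((ch, "noise_low", float(v)))
    return report


def detect_bad_trials(epochs: Epochs, n_sd: float = 3.0) -> QCReport:
    """Single-pass variance rule: flag trials with pooled variance greater
    than mean + 3 SD of the per-trial variances.  With zero spread
    (identical trials) nothing is flagged."""
    if epochs.n_trials < 3:
        raise ValueError("need at least 3 trials for the variance rule")
    var = epochs.data.reshape(epochs.n_trials, -1).var(axis=1)
    mu, sd = var.mean(), var.std()
    thresh = mu + n_sd * sd
    report = QCReport()
    if sd > 0:
        for i, v in enumerate(var):
            if v > thresh:
                report.bad_trials.append((i, float(v), float(thresh)))
    return report


def apply_filters(
    raw: RawRecording,
    notch_freqs=(50.0, 100.0, 150.0),
    band=(1.0, 150.0),
    order: int = 4,
    notch_q: float = 30.0,
) -> RawRecording:
    """Zero-phase notch (powerline + harmonics) and Butterworth band pass.

    A notch at the Nyquist frequency itself (150 Hz at fs=300) is invalid;
    150 Hz at fs=375 is fine.  DC is removed by the band pass.
    """
    fs = raw.fs
    nyq = fs / 2.0
    if not (0.0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} invalid for fs={fs} (Nyquist {nyq})")
    data = np.asarray(raw.data, dtype=float)
    for f0 in notch_freqs:
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} at or above Nyquist {nyq}")
        bn, an = signal.iirnotch(f0, notch_q, fs=fs)
        data = signal.filtfilt(bn, an, data, axis=-1)
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=-1)
    return dc_replace(raw, data=data)


def apply_hfc(raw: RawRecording, orientations: np.ndarray) -> tuple[RawRecording, np.ndarray]:
    """Project out spatially homogeneous fields.

    ``orientations`` is the (n_channels, 3) unit-axis matrix ``N`` (rows
    restricted to good channels if channels were removed); the projector
    ``P = I - N (N^T N)^-1 N^T`` is applied to the data and returned so the
    identical operator can be applied to lead fields.
    """
    n_mat = np.asarray(orientations, dtype=float)
    if n_mat.ndim != 2 or n_mat.shape[1] != 3:
        raise ValueError("orientation matrix must be (n_channels, 3)")
    if np.linalg.matrix_rank(n_mat) < 3:
        raise ValueError("orientation matrix is rank deficient")
    if n_mat.shape[0] != raw.data.shape[0]:
        raise ValueError("orientation rows must match data channels")
    proj = np.eye(n_mat.shape[0]) - n_mat @ np.linalg.solve(n_mat.T @ n_mat, n_mat.T)
    return dc_replace(raw, data=proj @ raw.data), proj


def segment(
    raw: RawRecording,
    window: tuple[float, float],
    event_type: str,
    channel_ids: np.ndarray | None = None,
) -> Epochs:
    """Cut trials around every trigger of ``event_type``.

    The sample count is ``round((end - start) * fs)`` for all trials;
    windows that would run off the recording are dropped with a log entry
    in ``dropped_trials``.
    """
    code = TRIGGER_CODES[event_type]
    onsets = raw.triggers["sample"][raw.triggers["code"] == code]
    if len(onsets) == 0:
        raise ValueError(f"no events of type {event_type!r} in recording")
    n_win = int(round((window[1] - window[0]) * raw.fs))
    offset = int(round(window[0] * raw.fs))
    chans = np.arange(raw.data.shape[0]) if channel_ids is None else np.asarray(channel_ids)

    trials, dropped = [], []
    for k, s0 in enumerate(onsets):
        a = int(s0) + offset
        b = a + n_win
        if a < 0 or b > raw.data.shape[1]:
            dropped.append(k)
            continue
        trials.append(raw.data[chans, a:b])
    if not trials:
        raise ValueError("every requested window falls outside the recording")
    return Epochs(
        data=np.array(trials),
        window=window,
        fs=raw.fs,
        event_type=event_type,
        channel_ids=chans,
        dropped_trials=dropped,
    )
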