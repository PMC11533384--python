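"""Phantom linearity / error statistics and cross-run comparison metrics.

The phantom analyses quantify how faithfully each sensor mode recovers a
known 17 Hz field: per 2-s on-epoch the Fourier magnitude at the 17 Hz bin
(exactly bin 34 at 0.5 Hz resolution) is extracted per channel with 2/N
amplitude normalisation, open-loop amplitudes are regressed against
closed-loop ones, and percentage errors relative to the zero-background
reference are summarised over the ten channels with the largest phantom
response.

The run-comparison machinery enumerates run pairs (all ordered cross pairs
between systems, all unordered pairs within a system), measures Euclidean
peak-voxel distances and Pearson timecourse correlations, and reports
mean ± SD tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import Epochs
from .source_recon import StatImage, find_peak

__all__ = [
    "ToneAmplitudeSet",
    "extract_tone_amplitude",
    "linearity_fit",
    "background_error_stats",
    "enumerate_pairs",
    "peak_distance",
    "timecourse_correlation",
    "summarize_comparison",
]


@dataclass
class ToneAmplitudeSet:
    """17-Hz component magnitude per (epoch, channel), tesla."""

    amplitudes: np.ndarray  # (n_epochs, n_channels)
    f0: float
    conditions: np.ndarray | None = None  # per-epoch drive (mA) or background (nT)
    mode: str | None = None


def extract_tone_amplitude(
    epochs: Epochs | np.ndarray,
    f0: float = 17.0,
    fs: float | None = None,
    conditions: np.ndarray | None = None,
    mode: str | None = None,
) -> ToneAmplitudeSet:
    """Amplitude-normalised DFT magnitude at ``f0`` per epoch and channel.

    ``f0`` must land exactly on a spectral bin (``f0 * N / fs`` integer);
    otherwise the epoch length is wrong for this protocol and an error is
    raised rather than silently interpolating or zero-padding.
    """
    if isinstance(epochs, Epochs):
        data, fs = epochs.data, epochs.fs
    else:
        data = np.asarray(epochs, dtype=float)
        if fs is None:
            raise ValueError("fs required for array input")
    n = data.shape[-1]
    bin_f = f0 * n / fs
    if abs(bin_f - round(bin_f)) > 1e-6:
        raise ValueError(
            f"{f0} Hz is not an exact bin for {n} samples at {fs} Hz; "
            "choose the epoch length so the tone falls on a bin"
        )
    k = int(round(bin_f))
    amps = 2.0 / n * np.abs(np.fft.rfft(data, axis=-1)[..., k])
    return ToneAmplitudeSet(amplitudes=amps, f0=f0, conditions=conditions, mode=mode)


def linearity_fit(open_amps: np.ndarray, closed_amps: np.ndarray):
    """Ordinary least squares of closed-loop vs open-loop amplitudes.

    Returns (slope, intercept, r_squared).  With matched simulations in
    zero background the slope is ~1: closed-loop operation does not change
    the measurement.
    """
    x = np.asarray(open_amps, dtype=float).ravel()
    y = np.asarray(closed_amps, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired amplitude sets must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def background_error_stats(
    amps: ToneAmplitudeSet,
    levels: np.ndarray,
    n_top: int = 10,
):
    """Percentage deviation from the zero-background amplitude.

    Channels are ranked by their mean zero-background amplitude; for the
    ``n_top`` strongest, the per-epoch error ``100 |A - A0| / A0`` is
    collected over all epochs at non-zero background levels.

    Returns (mean, sd, per-channel-epoch error array).
    """
    a = amps.amplitudes
    lv = np.asarray(levels, dtype=float)
    if lv.shape[0] != a.shape[0]:
        raise ValueError("levels must align with epochs")
    if n_top > a.shape[1]:
        raise ValueError("n_top exceeds channel count")
    zero = lv == 0.0
    if not np.any(zero):
        raise ValueError("no zero-background reference epochs")
    ref = a[zero].mean(axis=0)  # per-channel reference
    order = np.argsort(ref, kind="stable")[::-1]
    top = [int(ch) for ch in order if ref[ch] > 0][:n_top]  # zero-reference channels excluded
    if not top:
        raise ValueError("all reference amplitudes are zero")
    errs = 100.0 * np.abs(a[~zero][:, top] - ref[top]) / ref[top]
    return float(errs.mean()), float(errs.std()), errs


def enumerate_pairs(n_a: int, n_b: int | None = None, mode: str = "between"):
    """Run-pair enumeration.

    ``between``: all ordered (i, j) cross pairs, i in A, j in B — 36 for
    6 + 6 runs.  ``within``: all unordered distinct pairs — 15 for 6 runs.
    """
    if mode == "between":
        if n_b is None:
            raise ValueError("between mode needs two run counts")
        return list(product(range(n_a), range(n_b)))
    if mode == "within":
        return list(combinations(range(n_a), 2))
    raise ValueError(f"unknown mode {mode!r}")


def peak_distance(image_a: StatImage, image_b: StatImage) -> float:
    """Euclidean distance (mm) between the two images' peak voxels."""
    if image_a.grid.points.shape != image_b.grid.points.shape or not np.allclose(
        image_a.grid.points, image_b.grid.points
    ):
        raise ValueError("images are not on the same source grid")
    pa, _ = find_peak(image_a, image_a.polarity)
    pb, _ = find_peak(image_b, image_b.polarity)
    return float(np.linalg.norm(pa - pb) * 1000.0)


def timecourse_correlation(tc_a: np.ndarray, tc_b: np.ndarray) -> float:
    """Pearson correlation of two equal-length timecourses."""
    a = np.asarray(tc_a, dtype=float).ravel()
    b = np.asarray(tc_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("timecourses must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(a, b)[0])


def summarize_comparison(results: dict[tuple[str, str], list[float]]) -> pd.DataFrame:
    """Mean ± SD table over (measure, mode) keyed result lists.

    ``results`` maps ``(measure, mode)`` — e.g. ``("beta_distance_mm",
    "between")`` — to the per-pair values.  Single-pair entries report
    SD 0 with an ``n=1`` flag column.
    """
    if not results:
        raise ValueError("no comparison results")
    rows = []
    for (measure, mode), vals in results.items():
        v = np.asarray(vals, dtype=float)
        rows.append(
            {
                "measure": measure,
                "mode": mode,
                "n_pairs": v.size,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=0)) if v.size > 1 else 0.0,
                "single_pair": v.size == 1,
            }
        )
    return pd.DataFrame(rows)
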