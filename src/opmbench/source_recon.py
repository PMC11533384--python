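"""LCMV beamformer imaging, virtual electrodes, Hilbert envelopes, and
time-frequency spectrograms.

The linearly constrained minimum-variance (LCMV) spatial filter at source
location ``r`` with orientation ``theta`` and lead field ``l`` is

    w = C_reg^-1 l / (l^T C_reg^-1 l),

unit-gain at the target (``w^T l = 1``) and minimum-variance elsewhere.
``C_reg = C + lambda I`` with ``lambda`` equal to 1 % of the largest
eigenvalue of the sample covariance ``C``.  The source orientation is
optimised in the tangential plane (the spherical conductor is silent to
radial moments) by minimising ``l(theta)^T C_reg^-1 l(theta)``, i.e., a
2x2 generalised eigenvalue problem per grid point.

Images:

* pseudo-T — normalised active/control contrast of projected power,
  ``(Pa - Pc) / (Pa + Pc)``, bounded in [-1, 1];
* pseudo-Z — projected evoked power at one latency over the estimated
  noise power, ``(w^T b)^2 / (nu w^T w)`` with ``nu`` the smallest
  eigenvalue of the unregularised covariance (floored at ``lambda / 100``).

When homogeneous field correction has been applied to the data the stored
projector must be supplied here so lead fields live in the same projected
space; otherwise the unit-gain constraint is meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .forward_models import LeadField, SourceGrid
from .preprocess import Epochs

__all__ = [
    "CovarianceModel",
    "StatImage",
    "VirtualElectrode",
    "TFSResult",
    "compute_covariance",
    "lcmv_weights",
    "pseudo_t_image",
    "pseudo_z_image",
    "virtual_electrode",
    "hilbert_envelope",
    "compute_tfs",
    "find_peak",
    "default_tfs_bands",
]


@dataclass
class CovarianceModel:
    matrix: np.ndarray  # unregularised sample covariance
    regularised: np.ndarray
    lam: float  # 0.01 * max eigenvalue
    band: tuple[float, float] | None
    n_samples: int
    rank_warning: bool = False


@dataclass
class StatImage:
    grid: SourceGrid
    values: np.ndarray
    kind: str  # "pseudo_T" | "pseudo_Z"
    valid: np.ndarray
    polarity: str = "max"

    @property
    def peak(self) -> tuple[np.ndarray, float]:
        return find_peak(self, self.polarity)


@dataclass
class VirtualElectrode:
    location: np.ndarray
    weights: np.ndarray
    orientation: np.ndarray
    timecourses: np.ndarray  # (n_trials, n_samples) or (n_samples,)
    fs: float

    @property
    def average(self) -> np.ndarray:
        tc = np.atleast_2d(self.timecourses)
        return tc.mean(axis=0)


@dataclass
class TFSResult:
    bands: list[tuple[float, float]]
    times: np.ndarray
    values: np.ndarray  # (n_bands, n_samples) relative amplitude change
    baseline_window: tuple[float, float]


def compute_covariance(epochs: Epochs, band: tuple[float, float] | None = None) -> CovarianceModel:
    """Sample covariance over all concatenated trial samples, regularised
    with 1 % of its largest eigenvalue.  ``band`` is carried as metadata
    (the epochs are expected to be filtered to it already)."""
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    x = np.concatenate([epochs.data[i] for i in range(epochs.n_trials)], axis=-1)
    x = x - x.mean(axis=1, keepdims=True)
    n = x.shape[1]
    c = (x @ x.T) / (n - 1)
    lam = 0.01 * float(np.linalg.eigvalsh(c)[-1])
    return CovarianceModel(
        matrix=c,
        regularised=c + lam * np.eye(c.shape[0]),
        lam=lam,
        band=band,
        n_samples=n,
        rank_warning=n < c.shape[0],
    )


def _project_leadfields(lf: LeadField, projector: np.ndarray | None) -> np.ndarray:
    mats = lf.matrices
    if projector is None:
        return mats
    return np.einsum("dc,pcm->pdm", projector, mats)


def _tangential_basis(mats: np.ndarray) -> np.ndarray:
    """(n_pts, 3, 2) orthonormal basis of each point's source space.

    For the spherical conductor the radial direction is in the null space
    of the lead field, so the two dominant right-singular directions of
    ``L`` span the tangential plane; this needs no geometry and remains
    correct after HFC projection.
    """
    g = np.einsum("pcm,pcn->pmn", mats, mats)
    _, vecs = np.linalg.eigh(g)  # ascending eigenvalues
    return vecs[:, :, 1:]  # two largest


def _weights_all_points(
    lf: LeadField,
    cov: CovarianceModel,
    projector: np.ndarray | None = None,
):
    """Vectorised LCMV weights and optimal orientations for every point.

    Returns (weights (P, C), orientations (P, 3), valid (P,)).
    """
    mats = _project_leadfields(lf, projector)
    n_pts, n_ch, _ = mats.shape

    col_norm = np.linalg.norm(mats, axis=1)  # (P, 3)
    valid = col_norm.max(axis=1) > 1e-8 * max(col_norm.max(), 1e-300)

    cinv_l = np.linalg.solve(cov.regularised, mats.reshape(n_pts, n_ch, 3).transpose(1, 0, 2).reshape(n_ch, -1))
    cinv_l = cinv_l.reshape(n_ch, n_pts, 3).transpose(1, 0, 2)  # (P, C, 3)
    m = np.einsum("pcm,pcn->pmn", mats, cinv_l)  # L^T Cinv L per point

    t_basis = _tangential_basis(mats)  # (P, 3, 2)
    m2 = np.einsum("pmi,pmn,pnj->pij", t_basis, m, t_basis)
    vals2, vecs2 = np.linalg.eigh(m2)
    theta2 = vecs2[:, :, 0]  # minimiser of l^T Cinv l
    denom = vals2[:, 0]
    orient = np.einsum("pmi,pi->pm", t_basis, theta2)

    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.einsum("pcm,pm->pc", cinv_l, orient) / denom[:, None]
    valid &= np.isfinite(w).all(axis=1) & (denom > 0)
    w[~valid] = 0.0
    return w, orient, valid


def lcmv_weights(
    leadfield_matrix: np.ndarray,
    cov: CovarianceModel,
    projector: np.ndarray | None = None,
):
    """LCMV weights for a single grid point.

    Returns (weights (n_ch,), orientation (3,)).  Raises for a vanishing
    (radial-only / degenerate) lead field.
    """
    mats = np.asarray(leadfield_matrix, dtype=float)[None, :, :]
    lf = LeadField(grid=SourceGrid(points=np.zeros((1, 3))), matrices=mats, sphere_origin=np.zeros(3))
    w, orient, valid = _weights_all_points(lf, cov, projector)
    if not valid[0]:
        raise ValueError("degenerate lead field at requested point")
    return w[0], orient[0]


def _window_slice(epochs: Epochs, window: tuple[float, float]) -> slice:
    t0, t1 = epochs.window
    if window[0] < t0 - 1e-9 or window[1] > t1 + 1e-9:
        raise ValueError(f"window {window} outside epoch span {epochs.window}")
    a = int(round((window[0] - t0) * epochs.fs))
    b = int(round((window[1] - t0) * epochs.fs))
    return slice(a, b)


def _window_cov(epochs: Epochs, window: tuple[float, float]) -> np.ndarray:
    sl = _window_slice(epochs, window)
    x = epochs.data[:, :, sl]
    x = x - x.mean(axis=-1, keepdims=True)
    n = x.shape[0] * x.shape[2]
    return np.einsum("tcs,tds->cd", x, x) / max(n - 1, 1)


def pseudo_t_image(
    lf: LeadField,
    cov: CovarianceModel,
    epochs: Epochs,
    active_window: tuple[float, float],
    control_window: tuple[float, float],
    projector: np.ndarray | None = None,
    polarity: str = "max",
) -> StatImage:
    """Normalised active/control contrast of beamformer-projected power.

    ``T = (Pa - Pc) / (Pa + Pc)`` per grid point; 0 where both powers
    vanish.  Antisymmetric under window swap.  The peak polarity is
    ``min`` for desynchronisation contrasts (beta) and ``max`` for
    synchronisation (gamma).
    """
    w, _, valid = _weights_all_points(lf, cov, projector)
    ca = _window_cov(epochs, active_window)
    cc = _window_cov(epochs, control_window)
    pa = np.einsum("pc,cd,pd->p", w, ca, w)
    pc = np.einsum("pc,cd,pd->p", w, cc, w)
    s = pa + pc
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(s > 0, (pa - pc) / s, 0.0)
    t[~valid] = 0.0
    return StatImage(grid=lf.grid, values=t, kind="pseudo_T", valid=valid, polarity=polarity)


def pseudo_z_image(
    lf: LeadField,
    cov: CovarianceModel,
    evoked: np.ndarray,
    t_peak_sample: int,
    projector: np.ndarray | None = None,
) -> StatImage:
    """Evoked power at a single latency over estimated noise power."""
    w, _, valid = _weights_all_points(lf, cov, projector)
    b = np.asarray(evoked, dtype=float)[:, t_peak_sample]
    nu = max(float(np.linalg.eigvalsh(cov.matrix)[0]), cov.lam / 100.0)
    num = (w @ b) ** 2
    den = nu * np.einsum("pc,pc->p", w, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(den > 0, num / den, 0.0)
    z[~valid] = 0.0
    return StatImage(grid=lf.grid, values=z, kind="pseudo_Z", valid=valid, polarity="max")


def virtual_electrode(
    location: np.ndarray,
    lf: LeadField,
    cov: CovarianceModel,
    data: np.ndarray | Epochs,
    fs: float | None = None,
    projector: np.ndarray | None = None,
) -> VirtualElectrode:
    """Beamformer timecourse at (the grid point nearest to) ``location``.

    ``data`` may be continuous (n_ch, n_samples) or an :class:`Epochs`
    (projected per trial).
    """
    loc = np.asarray(location, dtype=float)
    d2 = np.linalg.norm(lf.grid.points - loc, axis=1)
    if d2.min() > 2.0 * lf.grid.spacing:
        raise ValueError("location is not on (or near) the source grid")
    idx = int(np.argmin(d2))
    w, orient = lcmv_weights(lf.matrices[idx], cov, projector)
    if isinstance(data, Epochs):
        tcs = np.einsum("c,tcs->ts", w, data.data)
        fs = data.fs
    else:
        if fs is None:
            raise ValueError("fs required for continuous data")
        tcs = w @ np.asarray(data, dtype=float)
    return VirtualElectrode(
        location=lf.grid.points[idx], weights=w, orientation=orient, timecourses=tcs, fs=fs
    )


def hilbert_envelope(timecourses: np.ndarray, average: bool = True) -> np.ndarray:
    """Magnitude of the analytic signal per trial, optionally trial-averaged.

    Input must already be band-limited to the band of interest.
    """
    tc = np.atleast_2d(np.asarray(timecourses, dtype=float))
    env = np.abs(hilbert(tc, axis=-1))
    return env.mean(axis=0) if average else env


def default_tfs_bands(fmax: float = 100.0) -> list[tuple[float, float]]:
    """Overlapping 2-Hz-wide bands from 2 Hz, hopped by 1 Hz."""
    return [(float(f), float(f + 2.0)) for f in np.arange(2.0, fmax - 1.0)]


def compute_tfs(
    ve_trials: np.ndarray,
    fs: float,
    times: np.ndarray,
    baseline_window: tuple[float, float],
    bands: list[tuple[float, float]] | None = None,
    order: int = 4,
) -> TFSResult:
    """Time-frequency spectrogram of relative oscillatory amplitude change.

    Per band: filter the broadband virtual-electrode trials (4th-order
    Butterworth, zero phase), take the Hilbert envelope, average over
    trials, subtract the baseline-window mean and divide by it.  A band
    whose baseline mean vanishes is zeroed.
    """
    tc = np.atleast_2d(np.asarray(ve_trials, dtype=float))
    if bands is None:
        bands = [b for b in default_tfs_bands() if b[1] < fs / 2.0]
    base = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not np.any(base):
        raise ValueError("baseline window outside trial span")
    rows = np.zeros((len(bands), tc.shape[-1]))
    for i, band in enumerate(bands):
        sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
        env = np.abs(hilbert(sosfiltfilt(sos, tc, axis=-1), axis=-1)).mean(axis=0)
        mu = env[base].mean()
        if mu > 0:
            rows[i] = (env - mu) / mu
    return TFSResult(bands=list(bands), times=np.asarray(times), values=rows, baseline_window=baseline_window)


def find_peak(image: StatImage, polarity: str = "max") -> tuple[np.ndarray, float]:
    """Extreme voxel under the configured polarity; ties break to the
    lowest linear index (argmax/argmin convention)."""
    vals = np.where(image.valid, image.values, np.nan)
    if np.all(np.isnan(vals)):
        raise ValueError("no valid voxels in image")
    if polarity == "max":
        idx = int(np.nanargmax(vals))
    elif polarity == "min":
        idx = int(np.nanargmin(vals))
    elif polarity == "abs":
        idx = int(np.nanargmax(np.abs(vals)))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return image.grid.points[idx].copy(), float(image.values[idx])
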