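"""OPM sensor physics: open-loop gain/cross-axis response, closed-loop
feedback linearisation, sensor noise, and inter-sensor cross talk.

An alkali-vapour magnetometer is linear only near zero field.  In *open
loop* the gain of each axis rolls off with the magnitude of the ambient
(background) field, modelled here as the zero-field-resonance Lorentzian

    g(b) = 1 / (1 + (b / Gamma)^2),

with half-width ``Gamma`` (nT), and large transverse backgrounds leak
signal between axes (cross-axis projection error, CAPE), modelled as a
first-order symmetric bilinear term with coefficient ``kappa``.  In
*closed loop* a negative feedback loop drives the on-board coils to hold
the cell near zero field; the feedback current is the measurement, so the
response stays linear until the coils saturate (±50 nT).

All fields handled here are expressed in each sensor's own axis frame
(axis order x, y, z as in the channel table) and in tesla; ``SensorState``
parameters use the field-customary nT / fT units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import bilinear, lfilter

from .forward_models import MU0

__all__ = [
    "SensorState",
    "open_loop_response",
    "closed_loop_response",
    "add_sensor_noise",
    "crosstalk_matrix",
]

NT = 1e-9  # tesla per nanotesla
FT = 1e-15  # tesla per femtotesla


@dataclass(frozen=True)
class SensorState:
    """Parameters of the OPM response model.

    Attributes
    ----------
    mode : str
        ``"open_loop"`` or ``"closed_loop"``.
    gain_linewidth : float
        ``Gamma``, half-width of the Lorentzian gain roll-off, nT.
    cape_coeff : float
        ``kappa``, dimensionless cross-axis leakage coefficient.
    loop_bandwidth : float
        First-order feedback-loop bandwidth, Hz (sensor bandwidth 135 Hz).
    noise_density : float
        One-sided white-noise amplitude spectral density, fT/sqrt(Hz).
    coil_range : float
        ± range of the on-board feedback coils, nT.
    open_loop_range : float
        Advisory ± open-loop operating range, nT (not enforced).
    """

    mode: str = "closed_loop"
    gain_linewidth: float = 12.0
    cape_coeff: float = 0.5
    loop_bandwidth: float = 135.0
    noise_density: float = 15.0
    coil_range: float = 50.0
    open_loop_range: float = 1.5

    def __post_init__(self):
        if self.mode not in ("open_loop", "closed_loop"):
            raise ValueError(f"unknown sensor mode {self.mode!r}")
        if self.gain_linewidth <= 0 or self.coil_range <= 0:
            raise ValueError("gain linewidth and coil range must be positive")
        if self.noise_density < 0:
            raise ValueError("noise density must be non-negative")

    def with_mode(self, mode: str) -> "SensorState":
        return replace(self, mode=mode)


def open_loop_response(
    true_field: np.ndarray,
    background: np.ndarray,
    state: SensorState,
) -> np.ndarray:
    """Open-loop measurement of per-sensor vector field timecourses.

    Parameters
    ----------
    true_field : (..., 3, n_samples) ndarray
        Total field (signal + background) in sensor axis frames, tesla.
    background : (..., 3, n_samples) ndarray
        Low-frequency background component, same shape, tesla.  Its
        magnitude sets the gain; its transverse components drive CAPE.
    state : SensorState
        Must be in ``open_loop`` mode.

    Notes
    -----
    Per axis ``a`` with cyclic triple ``(a, b, c)``::

        m_a = g(|B_bg|) * [B_a + kappa * (Bbg_b B_c + Bbg_c B_b) / (2 Gamma)]

    so the output equals the input exactly at zero background, the gain is
    1/2 at ``|B_bg| = Gamma``, and CAPE vanishes without background.
    """
    if state.mode != "open_loop":
        raise ValueError("state.mode must be 'open_loop'")
    b = np.asarray(true_field, dtype=float)
    bg = np.asarray(background, dtype=float)
    if b.shape != bg.shape:
        raise ValueError("true_field and background shapes differ")
    if b.shape[-2] != 3:
        raise ValueError("expected axis dimension of size 3")

    gamma = state.gain_linewidth * NT
    gain = 1.0 / (1.0 + (np.linalg.norm(bg, axis=-2, keepdims=True) / gamma) ** 2)

    cape = np.empty_like(b)
    for a in range(3):
        i, j = (a + 1) % 3, (a + 2) % 3
        cape[..., a, :] = bg[..., i, :] * b[..., j, :] + bg[..., j, :] * b[..., i, :]
    return gain * (b + state.cape_coeff * cape / (2.0 * gamma))


def _first_order_lag(b: np.ndarray, fs: float, bandwidth: float) -> np.ndarray:
    """First-order tracker with time constant ``tau = 1/(2 pi BW)``.

    Bilinear discretisation of ``H(s) = 1/(1 + s tau)``: unit DC gain and
    DC group delay exactly ``tau``, so a ramp of slew rate ``s`` is tracked
    with the analytic steady-state lag ``s * tau`` at any sampling rate
    (the physical loop runs much faster than the output sampling).
    """
    tau = 1.0 / (2.0 * np.pi * bandwidth)
    num, den = bilinear([1.0], [tau, 1.0], fs)
    return lfilter(num, den, b, axis=-1)


def closed_loop_response(
    true_field: np.ndarray,
    state: SensorState,
    fs: float,
    return_feedback: bool = False,
):
    """Closed-loop (feedback-linearised) measurement.

    The per-axis feedback field ``f(t)`` tracks the input with a discrete
    first-order lag of bandwidth ``loop_bandwidth`` and is clipped to the
    coil range; the small residual ``B - f`` is what the vapour cell
    actually experiences and passes through the open-loop response (its own
    low-pass-filtered value acting as the residual background).  The output
    is ``f + measured residual``, which approximates ``B`` to within the
    residual nonlinearity for drifts far below the loop bandwidth.

    Returns
    -------
    measured : ndarray like ``true_field``
    saturated : bool ndarray, per (sensor, axis)
        True where the demanded feedback exceeded ``coil_range``.
    """
    if state.mode != "closed_loop":
        raise ValueError("state.mode must be 'closed_loop'")
    b = np.asarray(true_field, dtype=float)
    if b.shape[-2] != 3:
        raise ValueError("expected axis dimension of size 3")

    f = _first_order_lag(b, fs, state.loop_bandwidth)
    limit = state.coil_range * NT
    saturated = np.any(np.abs(f) > limit, axis=-1)
    if np.any(saturated):
        np.clip(f, -limit, limit, out=f)

    residual = b - f
    # The cell sees only the residual; its slow component is the effective
    # background for the open-loop physics of the cell itself.
    residual_bg = _first_order_lag(residual, fs, min(1.0, state.loop_bandwidth))
    cell = open_loop_response(residual, residual_bg, state.with_mode("open_loop"))
    if return_feedback:
        return f + cell, saturated, f
    return f + cell, saturated


def add_sensor_noise(
    data: np.ndarray,
    state: SensorState,
    fs: float,
    seed: int,
) -> np.ndarray:
    """Add independent Gaussian white sensor noise per channel.

    A one-sided amplitude spectral density ``d`` (fT/sqrt(Hz)) sampled at
    ``fs`` corresponds to a per-sample standard deviation ``d*sqrt(fs/2)``.
    Each channel draws from its own ``(seed, channel)`` keyed stream, so
    noise commutes with channel permutation.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    data = np.asarray(data, dtype=float)
    if state.noise_density == 0.0:
        return data.copy()
    std = state.noise_density * FT * np.sqrt(fs / 2.0)
    flat = data.reshape(-1, data.shape[-1])
    out = np.empty_like(flat)
    for ch in range(flat.shape[0]):
        rng = np.random.default_rng([int(seed), ch])
        out[ch] = flat[ch] + std * rng.standard_normal(flat.shape[-1])
    return out.reshape(data.shape)


def crosstalk_matrix(
    array,
    coil_dipole_moment: float = 3.6,
) -> np.ndarray:
    """Fractional inter-sensor cross talk from the on-board coils.

    Each sensor's field-nulling coil assembly is modelled as a point
    magnetic dipole at the sensor cell, oriented along the sensor's radial
    axis, with moment ``coil_dipole_moment`` (A·m² per tesla of nulled
    field; the default corresponds to a coil producing its field at an
    effective ~9 mm scale).  Entry (i, j) is the field magnitude sensor i
    sees when sensor j nulls 1 nT, divided by 1 nT; the diagonal is zero.
    """
    pos = array.positions
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 sensors")
    moments = coil_dipole_moment * NT * array.axes[:, 2, :]  # dipole per 1 nT nulled

    diff = pos[None, :, :] - pos[:, None, :]  # j -> i
    dist = np.linalg.norm(diff, axis=-1)
    if np.any((dist < 1e-9) & ~np.eye(n, dtype=bool)):
        raise ValueError("coincident sensors")
    np.fill_diagonal(dist, np.inf)
    rhat = diff / dist[..., None]

    mdotr = np.einsum("jk,ijk->ij", moments, rhat)
    b = (MU0 / (4.0 * np.pi)) * (3.0 * mdotr[..., None] * rhat - moments[None, :, :]) / dist[..., None] ** 3
    frac = np.linalg.norm(b, axis=-1) / NT
    np.fill_diagonal(frac, 0.0)
    return frac
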