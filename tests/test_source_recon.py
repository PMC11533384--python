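"""Beamformer weights, stat images, virtual electrodes, envelopes, TFS."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from opmbench.preprocess import Epochs
from opmbench.source_recon import (
    StatImage,
    compute_covariance,
    compute_tfs,
    find_peak,
    hilbert_envelope,
    lcmv_weights,
    pseudo_t_image,
    pseudo_z_image,
    virtual_electrode,
)

FS = 375.0


def _epochs(data, window=(0.0, 2.0), fs=FS):
    return Epochs(
        data=np.asarray(data, dtype=float),
        window=window,
        fs=fs,
        event_type="circles",
        channel_ids=np.arange(np.asarray(data).shape[1]),
    )


def _nearest(grid, pos):
    return int(np.argmin(np.linalg.norm(grid.points - np.asarray(pos), axis=1)))


def _sim_epochs(lf, idx, orient, n_trials, burst, noise, seed, n=750):
    """Trials with a source at grid point ``idx`` active where ``burst``
    gates, plus white channel noise."""
    rng = np.random.default_rng(seed)
    l = lf.matrices[idx] @ orient
    data = np.empty((n_trials, l.size, n))
    sos = butter(4, (52, 65), btype="bandpass", fs=FS, output="sos")
    for tr in range(n_trials):
        s = sosfiltfilt(sos, rng.standard_normal(n))
        s /= s.std()
        s *= burst
        data[tr] = l[:, None] * s[None, :] + noise * rng.standard_normal((l.size, n))
    return _epochs(data)


# --- covariance --------------------------------------------------------------


def test_covariance_white_input_regularisation():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((40, 8, 500))
    cov = compute_covariance(_epochs(data))
    sigma2 = np.diag(cov.matrix).mean()
    assert np.allclose(cov.matrix, cov.matrix.T, atol=1e-12)
    # lambda = 1% of max eigenvalue ~= 1% of sigma^2 for white input
    assert cov.lam == pytest.approx(0.01 * np.linalg.eigvalsh(cov.matrix)[-1])
    assert np.allclose(np.diag(cov.regularised), np.diag(cov.matrix) + cov.lam)


def test_regularised_eigenvalues_shifted_exactly():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((10, 6, 300))
    cov = compute_covariance(_epochs(data))
    raw = np.linalg.eigvalsh(cov.matrix)
    reg = np.linalg.eigvalsh(cov.regularised)
    assert np.allclose(reg, raw + cov.lam, rtol=1e-10)


# --- weights -----------------------------------------------------------------


def test_unit_gain_constraint(helmet, coarse_leadfield):
    rng = np.random.default_rng(2)
    data = 1e-13 * rng.standard_normal((20, 192, 400))
    cov = compute_covariance(_epochs(data))
    idx = _nearest(coarse_leadfield.grid, [-0.03, 0.0, 0.05])
    w, orient = lcmv_weights(coarse_leadfield.matrices[idx], cov)
    l = coarse_leadfield.matrices[idx] @ orient
    assert abs(w @ l - 1.0) < 1e-8


def test_identity_covariance_weights_collinear_with_leadfield(coarse_leadfield):
    n_ch = coarse_leadfield.n_channels
    cov = compute_covariance(
        _epochs(np.random.default_rng(3).standard_normal((30, n_ch, 200)))
    )
    # overwrite with exact identity to test the closed form
    cov.matrix = np.eye(n_ch)
    cov.regularised = (1.01) * np.eye(n_ch)
    cov.lam = 0.01
    idx = _nearest(coarse_leadfield.grid, [0.0, 0.03, 0.05])
    w, orient = lcmv_weights(coarse_leadfield.matrices[idx], cov)
    l = coarse_leadfield.matrices[idx] @ orient
    cosang = (w @ l) / (np.linalg.norm(w) * np.linalg.norm(l))
    assert abs(abs(cosang) - 1.0) < 1e-10


def test_orientation_matches_brute_force_scan(helmet, coarse_leadfield):
    """Analytic tangential-plane orientation vs a 0.5-degree brute-force
    scan of beamformer output power."""
    idx = _nearest(coarse_leadfield.grid, [-0.03, 0.01, 0.05])
    lmat = coarse_leadfield.matrices[idx]
    # build covariance from a source at a known tangential orientation
    u, s, vt = np.linalg.svd(lmat, full_matrices=False)
    true_orient = vt[0]
    l_true = lmat @ true_orient
    rng = np.random.default_rng(4)
    n_tr, n = 30, 400
    data = np.empty((n_tr, lmat.shape[0], n))
    for tr in range(n_tr):
        src = rng.standard_normal(n)
        data[tr] = 1e-9 * l_true[:, None] * src[None, :] + 1e-16 * rng.standard_normal((lmat.shape[0], n))
    cov = compute_covariance(_epochs(data))
    _, orient = lcmv_weights(lmat, cov)

    # brute-force scan in the tangential plane
    t1, t2 = vt[0], vt[1]
    cinv = np.linalg.inv(cov.regularised)
    best_ang, best_p = None, -np.inf
    for ang in np.deg2rad(np.arange(0.0, 180.0, 0.5)):
        l = lmat @ (np.cos(ang) * t1 + np.sin(ang) * t2)
        p = 1.0 / (l @ cinv @ l)
        if p > best_p:
            best_p, best_ang = p, ang
    scan_orient = np.cos(best_ang) * t1 + np.sin(best_ang) * t2
    cosang = abs(orient @ scan_orient)
    assert np.degrees(np.arccos(min(cosang, 1.0))) < 2.0


# --- pseudo-T ----------------------------------------------------------------


def test_pseudo_t_null_contrast_near_zero(coarse_leadfield):
    rng = np.random.default_rng(5)
    data = 1e-13 * rng.standard_normal((60, 192, 750))
    cov = compute_covariance(_epochs(data))
    img = pseudo_t_image(coarse_leadfield, cov, _epochs(data), (0.0, 0.6), (1.1, 1.7))
    assert abs(img.values[img.valid].mean()) < 0.02


def test_pseudo_t_antisymmetric_under_window_swap(coarse_leadfield):
    rng = np.random.default_rng(6)
    data = 1e-13 * rng.standard_normal((20, 192, 750))
    data[:, :, :250] *= 3.0
    cov = compute_covariance(_epochs(data))
    a = pseudo_t_image(coarse_leadfield, cov, _epochs(data), (0.0, 0.6), (1.1, 1.7))
    b = pseudo_t_image(coarse_leadfield, cov, _epochs(data), (1.1, 1.7), (0.0, 0.6))
    assert np.array_equal(a.values, -b.values)


def test_pseudo_t_localises_gamma_burst(helmet, fine_leadfield):
    """Simulated gamma source active 0-0.6 s localises to within one grid
    step (4 mm) at high SNR."""
    lf = fine_leadfield
    true_pos = np.array([0.02, -0.04, 0.045])
    idx = _nearest(lf.grid, true_pos)
    _, _, vt = np.linalg.svd(lf.matrices[idx], full_matrices=False)
    t = np.arange(750) / FS
    burst = ((t >= 0.0) & (t < 0.6)).astype(float)
    ep = _sim_epochs(lf, idx, vt[0], n_trials=30, burst=1e-9 * burst, noise=2e-14, seed=7)
    cov = compute_covariance(ep)
    img = pseudo_t_image(lf, cov, ep, (0.0, 0.6), (1.1, 1.7), polarity="max")
    peak, _ = img.peak
    assert np.linalg.norm(peak - lf.grid.points[idx]) <= 0.004 + 1e-12


# --- pseudo-Z ----------------------------------------------------------------


def test_pseudo_z_zero_evoked_and_quadratic_scaling(coarse_leadfield):
    rng = np.random.default_rng(8)
    data = 1e-13 * rng.standard_normal((10, 192, 400))
    cov = compute_covariance(_epochs(data))
    zero = pseudo_z_image(coarse_leadfield, cov, np.zeros((192, 400)), 100)
    assert np.all(zero.values == 0.0)
    evoked = 1e-13 * rng.standard_normal((192, 400))
    z1 = pseudo_z_image(coarse_leadfield, cov, evoked, 100)
    z2 = pseudo_z_image(coarse_leadfield, cov, 2 * evoked, 100)
    assert np.allclose(z2.values, 4 * z1.values, rtol=1e-10)


def test_pseudo_z_localises_evoked_dipole_noise_free(helmet, fine_leadfield):
    """Noise-free evoked dipole, peak at 170 ms: Z-image peak within 4 mm."""
    lf = fine_leadfield
    idx = _nearest(lf.grid, [0.03, -0.05, 0.02])
    _, _, vt = np.linalg.svd(lf.matrices[idx], full_matrices=False)
    l = lf.matrices[idx] @ vt[0]
    t = np.arange(563) / FS  # 1.5 s window
    wave = np.exp(-0.5 * ((t - 0.170) / 0.02) ** 2)
    evoked = 1e-9 * l[:, None] * wave[None, :]
    # covariance built from the (signal-dominated) task data itself, as in
    # the evoked recipe; only a vanishing noise floor for conditioning
    rng = np.random.default_rng(9)
    data = evoked[None, :, :] + 1e-17 * rng.standard_normal((15, l.size, len(t)))
    cov = compute_covariance(_epochs(data, window=(0.0, 1.5)))
    img = pseudo_z_image(lf, cov, evoked, int(round(0.170 * FS)))
    peak, _ = img.peak
    assert np.linalg.norm(peak - lf.grid.points[idx]) <= 0.004 + 1e-12


# --- virtual electrode -------------------------------------------------------


def test_virtual_electrode_recovers_source_timecourse(coarse_leadfield):
    lf = coarse_leadfield
    idx = _nearest(lf.grid, [-0.02, 0.03, 0.04])
    _, _, vt = np.linalg.svd(lf.matrices[idx], full_matrices=False)
    l = lf.matrices[idx] @ vt[0]
    rng = np.random.default_rng(10)
    sos = butter(4, (13, 30), btype="bandpass", fs=FS, output="sos")
    n_tr, n = 20, 750
    truth = np.empty((n_tr, n))
    data = np.empty((n_tr, l.size, n))
    for tr in range(n_tr):
        s = sosfiltfilt(sos, rng.standard_normal(n))
        truth[tr] = s
        data[tr] = 1e-9 * l[:, None] * s[None, :] + 1e-16 * rng.standard_normal((l.size, n))
    ep = _epochs(data)
    cov = compute_covariance(ep)
    ve = virtual_electrode(lf.grid.points[idx], lf, cov, ep)
    r = np.corrcoef(ve.timecourses.ravel(), truth.ravel())[0, 1]
    assert abs(r) > 0.99


def test_virtual_electrode_linear_and_unit_gain(coarse_leadfield):
    lf = coarse_leadfield
    idx = _nearest(lf.grid, [0.0, -0.03, 0.05])
    rng = np.random.default_rng(11)
    base = 1e-13 * rng.standard_normal((8, 192, 300))
    cov = compute_covariance(_epochs(base))
    loc = lf.grid.points[idx]
    ve_a = virtual_electrode(loc, lf, cov, _epochs(base))
    ve_b = virtual_electrode(loc, lf, cov, _epochs(2 * base))
    assert np.allclose(2 * ve_a.timecourses, ve_b.timecourses, rtol=1e-12)
    # unit gain: projecting the point's own pattern at unit moment gives 1
    l = lf.matrices[idx] @ ve_a.orientation
    assert ve_a.weights @ l == pytest.approx(1.0, abs=1e-8)


def test_virtual_electrode_outside_head_rejected(coarse_leadfield):
    cov = compute_covariance(
        _epochs(np.random.default_rng(1).standard_normal((5, 192, 100)))
    )
    with pytest.raises(ValueError):
        virtual_electrode([0.5, 0.5, 0.5], coarse_leadfield, cov, np.zeros((192, 100)), fs=FS)


# --- envelope and TFS --------------------------------------------------------


def test_hilbert_envelope_of_sinusoid():
    t = np.arange(2000) / FS
    x = 3.0 * np.sin(2 * np.pi * 21.0 * t)
    env = hilbert_envelope(x)
    mid = slice(200, -200)
    assert np.abs(env[mid] - 3.0).max() < 0.03
    assert np.all(env >= 0)


def test_hilbert_envelope_tracks_amplitude_modulation():
    t = np.arange(4000) / FS
    mod = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
    x = mod * np.sin(2 * np.pi * 30.0 * t)
    env = hilbert_envelope(x)
    mid = slice(300, -300)
    r = np.corrcoef(env[mid], mod[mid])[0, 1]
    assert r > 0.99


def test_tfs_stationary_signal_near_zero():
    rng = np.random.default_rng(12)
    trials = rng.standard_normal((250, 1125))
    times = np.arange(1125) / FS
    tfs = compute_tfs(trials, FS, times, baseline_window=(2.0, 2.9),
                      bands=[(8, 12), (13, 30), (30, 50)])
    inner = (times > 0.3) & (times < 2.7)  # away from filter edge transients
    assert np.abs(tfs.values[:, inner]).mean() < 0.05
    assert abs(tfs.values[:, inner].mean()) < 0.05


def test_tfs_recovers_erd_depth():
    """Beta amplitude dropping by 50 % during 'movement' shows up as ~-0.5
    in the 13-30 Hz rows."""
    rng = np.random.default_rng(13)
    fs = FS
    n = int(8 * fs)
    times = np.arange(n) / fs
    sos = butter(4, (13, 30), btype="bandpass", fs=fs, output="sos")
    trials = np.empty((60, n))
    env = np.where((times > 0.5) & (times < 4.0), 0.5, 1.0)
    for tr in range(60):
        trials[tr] = env * sosfiltfilt(sos, rng.standard_normal(n))
    tfs = compute_tfs(trials, fs, times, baseline_window=(6.5, 7.5),
                      bands=[(13, 15), (17, 19), (21, 23), (25, 27), (28, 30)])
    move = (times > 1.0) & (times < 3.5)
    assert abs(tfs.values[:, move].mean() - (-0.5)) < 0.1
    base = (times >= 6.5) & (times <= 7.5)
    assert np.abs(tfs.values[:, base].mean(axis=1)).max() < 1e-10 * max(
        1.0, np.abs(tfs.values).max()
    )


# --- peaks -------------------------------------------------------------------


def _image(values, grid, polarity="max"):
    return StatImage(grid=grid, values=np.asarray(values, dtype=float),
                     kind="pseudo_T", valid=np.ones(len(values), dtype=bool),
                     polarity=polarity)


def test_find_peak_single_extremum(coarse_grid):
    vals = np.zeros(coarse_grid.n_points)
    vals[37] = 2.0
    loc, v = find_peak(_image(vals, coarse_grid), "max")
    assert v == 2.0
    assert np.array_equal(loc, coarse_grid.points[37])


def test_find_peak_tie_breaks_to_lowest_index(coarse_grid):
    vals = np.zeros(coarse_grid.n_points)
    vals[[10, 40]] = 1.0
    loc, _ = find_peak(_image(vals, coarse_grid), "max")
    assert np.array_equal(loc, coarse_grid.points[10])


def test_find_peak_min_equals_max_of_negated(coarse_grid):
    rng = np.random.default_rng(14)
    vals = rng.standard_normal(coarse_grid.n_points)
    loc_min, v_min = find_peak(_image(vals, coarse_grid), "min")
    loc_max, v_max = find_peak(_image(-vals, coarse_grid), "max")
    assert np.array_equal(loc_min, loc_max)
    assert v_min == -v_max
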