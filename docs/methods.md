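# Methods

`opmbench` simulates a wearable 192-channel triaxial OPM-MEG system — 64
optically-pumped magnetometers in a rigid helmet, each measuring the field
along three orthogonal axes — and implements the analysis chain used to
validate such systems: quality control, filtering, homogeneous field
correction (HFC), LCMV beamformer imaging, virtual electrodes,
time-frequency spectrograms, and phantom/run-comparison statistics.
Everything runs on synthetic data; the generator's defaults encode the
study conditions listed below.

## Array geometry

Sensors are placed on a Fibonacci lattice restricted to polar angles
≤ 105° (helmet coverage; no face or neck sensors) on a sphere of radius
`head_radius + standoff`, defaults 90 mm + 6.5 mm. The standoff and cap
extent are configuration defaults, not claims about a particular helmet:
real sensor coordinates for rigid helmets are product-specific. Each
sensor's third axis is radial, the first two tangential; channel ordering
is sensor-major with axes x, y, z. The seed rotates the lattice
azimuthally, so builds are bitwise reproducible.

## Forward models

Neural sources are current dipoles in a homogeneous conducting sphere,
evaluated with the closed-form (Sarvas) solution. Two exact properties
anchor the tests: radial dipole moments are externally silent, and the
external field is conductivity-independent. The sphere model was chosen
over a realistic-surface corrected-sphere method because the synthetic
setting has no anatomy; the conductor model is isolated behind
`dipole_field_sphere` so a corrected variant can be added.

The phantom is a single-turn isosceles triangular coil (5 mm base, 45 mm
height) in air — a dry phantom, so no volume-current term. Segment fields
use the exact finite-wire Biot–Savart closed form. The coil pose places
the base ~2.5 cm below the helmet crown so that the strongest channel
sees ~230 pT at 1 mA drive (the drive amplitudes 0.01–1 mA then span the
20–200 pT regime); the pose is a configuration default.

Lead fields are per-grid-point `(n_channels × 3)` gain matrices on a
regular 4 mm lattice restricted to the sphere interior. The grid point at
the sphere centre is externally silent and is marked invalid during
imaging.

## Sensor model

Open loop: each axis reads
`m_a = g(|B_bg|)·[B_a + κ(B_bg,b·B_c + B_bg,c·B_b)/(2Γ)]` with the
zero-field-resonance Lorentzian gain `g(b) = 1/(1+(b/Γ)²)`. The gain
half-width defaults to Γ = 12 nT; true linewidths for commercial triaxial
sensors are unpublished, and with this value the simulated mean open-loop
amplitude error over a 0–8 nT sweep is ~12 %, the same order as errors
reported for helmet-mounted arrays (≈14 %). Cross-axis projection error
(CAPE) is modelled as the symmetric bilinear leakage term above with
κ = 0.5 (dimensionless, free parameter): it vanishes at zero background
and grows with transverse background, which is the qualitative behaviour
the tests assert.

Closed loop: a per-axis negative feedback field `f(t)` tracks the input
with a first-order lag of bandwidth 135 Hz (the sensor bandwidth; real
loop dynamics are not published, so the lag is an abstraction) and is
clipped to the ±50 nT on-board coil range, setting a saturation flag when
exceeded. The discrete lag uses the bilinear transform of
`1/(1+sτ)`, whose DC group delay is exactly `τ = 1/(2π·135 Hz)` at any
sampling rate — the physical loop runs far above the output rate, and
this discretisation preserves the analytic ramp-lag `slew × τ`. The small
residual `B − f` passes through the open-loop physics of the cell (its
low-pass-filtered value acting as residual background); the output is
`f` plus the measured residual. For drifts well below the loop bandwidth
and fields within the coil range, the output reproduces the input to
≪ 0.1 %.

Sensor noise is white and Gaussian at 15 fT/√Hz (one-sided amplitude
spectral density), i.e. per-sample σ = 15 fT·√(fs/2). Each channel draws
from a `(seed, channel)`-keyed stream so noise commutes with channel
permutation. Cross talk between sensors is a geometric model: each
sensor's nulling coils are a point magnetic dipole along its radial axis,
scaled so the coil produces its field at an effective ~9 mm scale; row
maxima on the default helmet are ≲2 %, the order measured for real
arrays.

## Study conditions (synthetic-data defaults)

- **Visuo-motor paradigm**: 60 circles trials (1.0 s stimulus), 120
  faces (0.5 s), 25 catch/button-press (0.8 s), pseudo-randomised, each
  followed by a rest drawn uniformly from 1.25 ± 0.2 s (the protocol
  quotes mean ± excursion without naming a distribution; uniform is
  assumed). With the jitter at its mean the protocol lasts 396.25 s,
  i.e. 396 whole seconds. The catch-trial rest uses the same jitter —
  required for that total to come out.
- **Phantom amplitude sweep**: 17 Hz sinusoidal drive, 2 s on / 1 s off,
  amplitudes [0.01, 0.02, 0.05, 0.08, 0.1, 0.2, 0.5, 0.8, 1] mA cycled
  eight times = 72 on-epochs. (Published protocol text arrives at 64
  epochs per channel; 9 × 8 = 72, and the generator follows the stated
  protocol.)
- **Phantom background sweep**: 1 mA drive, 5 epochs at each background
  level 0.0–8.0 nT in 0.1 nT steps (81 levels, 405 epochs), the field
  uniform and vertical, stepped between blocks.
- **Sit-to-stand**: 8 s trials cued by alternating 1 s tones. The head
  moves through the static shielded-room field, modelled as a
  raised-cosine background excursion of 2.5 nT over the first ~2 s of
  each trial (rising on stand trials, falling on sit trials) on top of a
  constant 3 nT vertical ambient field. The ambient term reflects that
  this paradigm is run without degaussing or active nulling, where
  residual room fields around the head are of order 3 nT; without it the
  open-loop gain error at a bare 2.5 nT excursion would be only ~4 % and
  the open/closed contrast the paradigm exists to demonstrate would
  largely vanish. The beta source desynchronises during the first 4 s of
  each trial. 20 trials, 1500 Hz.
- **Cross-site motor block**: 3 s move / 3 s rest, 50 trials per run,
  two runs (100 trials), 375 Hz.

Source roles: `beta_motor` is 13–30 Hz Gaussian noise whose envelope
drops by the modulation depth (default 0.5) during movement windows with
raised-cosine edges (0.1 s); `gamma_visual` is 52–65 Hz narrowband noise
whose envelope rises during circles stimuli; `evoked_fusiform` is a
deterministic biphasic waveform peaking 170 ms after each face onset;
`brain_noise` dipoles carry 1/f amplitude spectra. Baseline moments
default to 5–10 nAm RMS — ordinary cortical source strengths.

What the generator does *not* emulate: cardiac/ocular artefacts,
realistic interference spectra beyond homogeneous drift plus an optional
50 Hz line, inter-sensor calibration differences, co-registration error,
or anatomy. Tests passing here therefore demonstrate the correctness of
the analysis machinery under the stated sensor physics, not performance
on real recordings.

## Preprocessing

Spectra are Welch averaged periodograms (2 s Hann segments, 50 % overlap:
0.5 Hz resolution resolves the QC band comfortably). Channels whose mean
60–80 Hz amplitude spectral density is > 30 or < 7 fT/√Hz are removed
(noisy, or dead/disconnected). Bad trials: pooled variance (over channels
and samples) more than 3 SDs above the mean trial variance, single pass;
with zero spread nothing is flagged. Variance is pooled rather than
per-channel-aggregated — a documented choice. Filters are 50/100/150 Hz
notches plus a 1–150 Hz 4th-order Butterworth band pass, applied
forward-backward; zero-phase filtering preserves the 170 ms evoked
latency. The pipeline order is fixed (QC → filter → HFC → segment).

HFC removes the 3-dimensional channel-space subspace of spatially uniform
fields via `P = I − N(NᵀN)⁻¹Nᵀ` with `N` the (good-channel) orientation
matrix. The projector is returned and is always applied to lead fields
before beamforming — without this the unit-gain constraint would be
stated in the wrong space.

## Beamforming

Covariance uses all concatenated trial samples with Tikhonov
regularisation λ = 1 % of the largest eigenvalue. LCMV weights are
`w = C_reg⁻¹l / (lᵀC_reg⁻¹l)`; the source orientation maximises output
power in the tangential plane — equivalently the 2×2 generalised
eigenvalue problem minimising `lᵀC_reg⁻¹l` over the two dominant
right-singular directions of the (projected) lead field. Using the
singular directions rather than geometric tangents keeps the procedure
correct after HFC projection.

The pseudo-T statistic is the normalised difference
`(Pa − Pc)/(Pa + Pc)` of projected power between equal-length active and
control windows — bounded in [−1, 1], scale-free, antisymmetric under
window swap; this definition is a convention (the alternative
`(Pa − Pc)/2ν` is not used). Note a consequence: for a single noise-free
source the ratio is identical at every voxel, so noise-free localisation
checks go through the pseudo-Z image, which remains well-posed. Pseudo-Z
is `(wᵀb̄(t_peak))²/(ν·wᵀw)` with noise power ν the smallest eigenvalue
of the unregularised covariance, floored at λ/100 — also a documented
convention, since "estimated noise power" admits several estimators.
Peak polarity is bound to each contrast preset: `min` for beta
desynchronisation, `max` for gamma and evoked responses; ties break to
the lowest linear voxel index.

Window/band recipes per trial type: circles 52–65 Hz, 0–0.6 vs
1.1–1.7 s; faces 2–40 Hz, pseudo-Z at 170 ms; catch 13–30 Hz, −0.3–0.3
vs 0.8–1.4 s; sit-to-stand 13–30 Hz, 2–3 vs 6.5–7.5 s; motor block
13–30 Hz, 0.5–1.5 vs 3.5–4.5 s.

TFS: the broadband virtual electrode is filtered into overlapping 2 Hz
bands hopped by 1 Hz from 2 Hz (band widths are a convention — only
"overlapping" is prescribed by the recipes this follows), Hilbert
enveloped, trial-averaged, baseline-corrected by subtracting and dividing
by the control-window mean. A band with zero baseline mean is zeroed.

## Phantom statistics

17 Hz amplitudes are extracted per 2 s on-epoch as the `2/N`-normalised
DFT magnitude at the exact 17 Hz bin (bin 34 at 0.5 Hz resolution); a
non-bin frequency is an error, never silently interpolated. Linearity is
ordinary least squares of closed-loop against open-loop amplitudes.
Background error statistics subtract each channel's zero-background
reference amplitude and report mean ± SD percentage error over the ten
channels with the largest zero-background closed-loop response (which
condition defines "largest" is unstated in the protocols this mirrors;
zero-background is used) and all non-zero levels. Run comparisons:
between-system pairs are the full ordered cross product (6 × 6 = 36),
within-system pairs unordered (15 for 6 runs), matching the published
counting convention.

## Numerical choices and degenerate inputs

- Dipole at the sphere centre, or with radial moment: zero field, not an
  error. Evaluation points inside the conductor or on a coil wire raise.
- Grid points with vanishing lead fields are marked invalid and excluded
  from peaks.
- `Pa + Pc = 0` yields pseudo-T 0 at that voxel.
- Identical trial variances flag nothing; zero-variance timecourses make
  Pearson correlation an error, not NaN.
- Background-sweep simulation proceeds level-by-level (the protocol
  steps the field between blocks; the ~1 ms loop transient at a step is
  negligible against 2 s epochs), keeping memory flat.
- Problem sizes in the test suite: localisation uses a 4 mm grid of
  ~28k points within 75 mm radius and 30 trials per image; the
  sit-to-stand runs use 20 trials at 1500 Hz. These are the package's
  validation sizes; all are configurable.

## Known limitations

- CAPE's functional form and magnitude are free-parameter models; only
  its contract (zero without background, growth with transverse
  background) is validated.
- The closed-loop model has no noise-floor penalty, loop delay jitter,
  or quantisation; the residual closed-loop error observed on real
  systems beyond noise and finite loop gain is not modelled.
- Cross talk uses the appendix-free geometric dipole-coupling model; no
  measurement protocol is implemented.
- No manual/visual rejection, ICA, or movement regression; only the
  automatic QC rules plus a manual exclusion list.
- Statistical thresholding of images is out of scope (descriptive
  mean ± SD reporting only).
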