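# Methods

`qpdclass` is a simulation-and-analysis pipeline for a question from optical
trapping practice: can a trapped microsphere be identified — by size and by
material — from nothing but the temporal fluctuations of the quadrant
photodetector (QPD) signals that a standard single-beam optical tweezers
setup already records?  The package simulates the physics, extracts a
compact spectral representation of short signal windows, and benchmarks
standard classifiers under a leakage-safe cross-validation protocol.

## Physical model

A bead of radius $a$ held in an optical trap is modelled as an overdamped
Brownian particle in a 3-D harmonic potential.  Per axis $i \in \{x,y,z\}$:

$$\mathrm{d}x_i = -\frac{k_i}{\gamma} x_i\,\mathrm{d}t
  + \sqrt{\frac{2 k_B T}{\gamma}}\,\mathrm{d}W_t ,$$

with $k_i$ the trap stiffness (N/m), $\gamma = 6\pi\eta a$ the Stokes drag
of a sphere in a fluid of viscosity $\eta$, $T$ the temperature and $W_t$ a
Wiener process.  The inertial term is dropped: at these scales the particle
Reynolds number is far below one and the momentum relaxation time
($m/\gamma \sim$ µs) is invisible at a 10 kHz sampling rate.  The three
axes are independent (diagonal stiffness tensor).

Two classical consequences of this model are used as the pipeline's
internal truth conditions:

* **Equipartition**: the stationary variance of each axis is
  $\langle (x - x_{eq})^2\rangle = k_B T / k_i$, so
  $k_i = k_B T / \mathrm{var}(x)$.
* **Lorentzian power spectrum**: the one-sided PSD is
  $S_{xx}(f) = k_B T / \big(\pi^2\gamma (f_0^2 + f^2)\big)$ with corner
  frequency $f_0 = k_i / (2\pi\gamma)$.  Fitting the measured spectrum
  recovers $f_0$ and hence $k_i = 2\pi f_0 \gamma$.

### Integration

The default integrator is Euler–Maruyama with time step
$\Delta t = 1/(f_s \cdot \text{substeps})$.  Because the overdamped
equation per axis is an Ornstein–Uhlenbeck process, the discrete update is
an AR(1) recursion, which we evaluate with a vectorised IIR filter — a
120 s, three-axis trace at 10 kHz takes well under a second.  The exact OU
update ($c = e^{-\theta\Delta t}$ instead of $1-\theta\Delta t$) is
available as `integrator="exact"` and serves as an internal oracle for the
default integrator in the tests.  At the default parameters the Euler
stability margin is enormous ($\theta\Delta t \sim 4\times10^{-3}$ against
the stability bound of 2); the simulator raises an explicit error with a
remedy (more substeps) if a configuration crosses it.  The first second of
every trajectory is burn-in and discarded so that the recorded trace is
stationary despite the $x(0)=0$ initial condition (a bead is trapped long
before recording starts).

### Detector model

The QPD is modelled as a linear transfer: $X = R_{xy} x + \varepsilon$,
$Y = R_{xy} y + \varepsilon$, $\mathrm{SUM} = V_0 + R_z z + \varepsilon$,
with additive white Gaussian noise $\varepsilon$ of standard deviation
`noise_sd` per channel and sample.  The axial ($z$) term gives SUM a
fluctuating, particle-dependent component; axial stiffness defaults to
0.2× transverse, the usual order for a single-beam gradient trap.  The
detector's real bandwidth (150 kHz class hardware) far exceeds the 10 kHz
acquisition rate, so no detector filtering is modelled.  The "no particle"
class is rendered as baseline plus noise: an empty trap scatters nothing
that moves.

Defaults: $R_{xy} = 10^7$ V/m, $R_z = 2\times10^6$ V/m, $V_0 = 5$ V,
`noise_sd` = 10 mV.  With these, a trapped bead's transverse fluctuations
(tens of nm RMS) map to a few hundred mV — a realistic signal-to-noise for
back-focal-plane detection — while the empty-trap channels are pure noise.

### Particle roster and stiffness defaults

The six default classes are polystyrene spheres of 3, 4 and 8 µm diameter
(n = 1.5731 at 976 nm), PMMA spheres of 3 and 8 µm (n = 1.4824), and the
empty trap, all in water (n = 1.3270, η = 8.9×10⁻⁴ Pa·s, T = 298 K).

No published per-class stiffness or corner-frequency values exist for this
kind of study, so the per-class stiffness table is an explicit simulation
convention, configurable in `default.yaml`.  The defaults were chosen on
two physics grounds: stiffness increases with the particle/medium
refractive-index contrast (so PS > PMMA at equal size), and the material
dependence steepens for beads much larger than the focal spot (ray-optics
regime), while the transverse stiffness decreases slowly with size at
fixed power.  Numerically (x-axis, N/m → corner frequency):

| class  | k_x     | f0,x (Hz) | f0,z (Hz) |
|--------|---------|-----------|-----------|
| ps3    | 5.0e-6  | 31.6      | 6.3       |
| ps4    | 4.5e-6  | 21.3      | 4.3       |
| pmma3  | 3.5e-6  | 22.1      | 4.4       |
| ps8    | 4.0e-6  | 9.5       | 1.9       |
| pmma8  | 1.6e-6  | 3.8       | 0.8       |
| none   | 0       | —         | —         |

This placement deliberately reproduces the qualitative confusion structure
such an experiment shows: the 3 µm PS/PMMA pair and 4 µm PS have nearby
transverse corners (hard), the two 8 µm materials are well separated in the
transverse channels (easy with X/Y), and in the axial channel — the only
dynamics SUM sees — the material pairs collapse below the 2 Hz resolution
of a 500 ms segment, so SUM-only classification degrades exactly where the
transverse channels carry the discriminating information.

## Calibration estimators

* `equipartition_stiffness`: $k = k_B T/\mathrm{var}(x)$ with the sample
  mean standing in for the equilibrium position and the unbiased variance.
* `estimate_psd`: Bartlett block-averaged periodogram (rectangular window,
  zero overlap, default 8 blocks), DC bin removed, density normalisation
  (`sum(power)·df ≈ var`).  Averaging matters: a raw periodogram bin has
  100% relative noise, which would dominate a least-squares fit.
* `fit_lorentzian`: fits $S(f) = A/(f_0^2+f^2)$ in log-power space with
  uniform weights (periodogram noise is multiplicative, so log residuals
  are approximately homoscedastic), over a fit band defaulting to
  [1 Hz, f_s/10] — above slow drift, and far enough below Nyquist that
  the aliased spectral tail (which lies above the Lorentzian and biases
  the fitted corner upward; at f_s/4 the bias is several percent) is
  negligible.  The
  initial $f_0$ is the half-plateau frequency.  A fit whose corner lands
  outside the band (e.g. on a white, cornerless spectrum) raises a fit
  failure rather than returning a number.

Applied to voltage traces rather than metres, both estimators return
stiffness up to the squared responsivity; within this package they are used
on simulated position traces as the parameter-recovery check of the
simulator (programmed k in → estimated k out, both routes, within 10%).

## Feature extraction

Each trace is cut into non-overlapping 500 ms segments (240 per 120 s
acquisition; trailing remainder discarded).  Per channel, a segment is
mapped to the magnitude of its one-sided FFT with the DC bin removed —
5000 samples → 2500 magnitudes; 3 channels × 5000 points → 3 × 2500.  The
magnitude (not power, not complex parts) is the minimal phase-invariant
representation; the phase of a Brownian signal carries no class
information.  No window is applied: Brownian spectra are broadband and
smooth, so leakage is not a concern.  Removing bin 0 makes features exactly
invariant to constant channel offsets (the SUM baseline in particular).

An independent 2-component PCA per channel (mean-centring only, no
variance scaling) reduces each spectrum to two scores: 6 features per
segment in 3-channel mode, 2 in SUM-only mode.  Component signs are fixed
by requiring the largest-magnitude loading positive, so models and
features are bit-reproducible.  Only bin 0 is treated as the uninformative
"continuum"; removing a wider low-frequency band is possible by slicing
the spectra but is not the default.

PCA is fitted on the training fold's spectra only and applied to the test
fold (`pca_scope: train_only`); a `global` scope — one PCA over the full
dataset before splitting — is available to reproduce the leakier reading
of the protocol.  Within a fold, the inner hyper-parameter search reuses
the outer fold's projection rather than refitting PCA per inner split:
the leakage unit the protocol protects is the acquisition signal, and
refitting a 3×2500-dimensional PCA for every grid point × inner fold would
multiply cost for no change in the train/test separation of the outer
evaluation.

## Classification protocol

Segments from one acquisition are strongly correlated, so cross-validation
is **signal-wise**: with 6 signals per class, each of 6 outer folds holds
out exactly one signal per class (all 240 of its segments) as the test
set.  Hyper-parameters are tuned by an inner signal-wise CV (5 folds, or
fewer if the training fold cannot support 5) on the training signals only;
the winning grid point is refit on the whole training fold and evaluated
once on the held-out signals.  Accuracy is segment-level.  Fold integrity
(no signal on both sides; test folds partition the signals) is asserted on
every run.

Families and grids (small, standard; the protocol, not the grids, is the
point): random forest — trees {100, 300}, depth {∞, 10}; RBF-SVM —
C {0.1, 1, 10, 100}, γ {scale, 0.01, 0.1}; KNN — k {1, 3, 5, 9},
Euclidean; MLP — one hidden layer {16, 64}.  SVM/KNN/MLP see z-scored
features (scaler fitted on the training fold); random forests use raw
features.  The MLP stops on a training-loss plateau
(`n_iter_no_change=20`, `max_iter=500`) rather than a held-out validation
split: at these fold sizes a 10% random validation split is both tiny and
not signal-aware, and makes the optimiser stop prematurely.  Grid points
infeasible at a given fold size (e.g. more neighbours than training
samples) are skipped during tuning.  Ties in the grid search resolve to
the earlier grid point; KNN prediction ties resolve to the first label in
sorted order — both for determinism.

Per family the report carries mean/best/worst fold accuracy and a
confusion matrix accumulated over folds and row-normalised at the end.
`compare_channel_modes` runs the 3-channel and SUM-only benchmarks on
identical folds (same split seed), giving a paired comparison.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the method relies on —
per-class Lorentzian spectra with class-dependent corners and amplitudes,
detector noise, an empty-trap class, repeat acquisitions with independent
noise realisations.  It does **not** emulate: laser power drift or
low-frequency intensity noise in SUM, detector nonlinearity and per-class
responsivity differences, size dispersion within a particle batch, axial
anharmonicity, or hydrodynamic memory effects.  Consequently, passing the
benchmark's ordering properties here shows that the pipeline extracts the
dynamics-borne class information under the stated model; it does not
certify accuracy numbers on any particular instrument, which is why
absolute accuracies are reported but only orderings (3-channel > SUM-only,
perfect empty-trap recall, material confusion concentrated in SUM-only
mode) are asserted.

## Problem sizes

Unit and property tests run on seconds-long traces; the physics-recovery
checks use the full 120 s × 10 kHz acquisition they are stated for.  The
benchmark acceptance checks and the acceptance script run the complete
6-class × 6-signal design with acquisitions shortened to 10 s
(720 segments), which preserves every qualitative property of the
full-scale study; the committed `default.yaml` keeps the full 120 s design
(8,640 segments) for end-to-end runs via `qpdclass run`.

## Numerical and degenerate-input conventions

* Seeds: one base seed derives every stage seed (SeedSequence spawn keys),
  and each trace's integrator and detector noise streams get independent
  seeds derived from (base, class index, signal index, stream).  All
  derived seeds are < 2³¹.
* Zero-temperature or zero-noise inputs are valid and exercised in tests
  (frozen trajectory; exact affine detector images).
* Zero-variance positions, empty class lists, missing stiffness-table
  labels, sub-minimal PSD fit bands, unstable integrator steps, and
  malformed trace files raise typed errors naming the offending quantity.
* Trace CSVs serialise floats at 17 significant digits and are parsed with
  round-trip precision, so write→read is bit-exact.
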