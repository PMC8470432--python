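# qpdclass

Identify optically trapped microparticles from the temporal dynamics of
their quadrant-photodetector (QPD) signals.

A single-beam optical tweezers setup records three voltage channels — X
and Y (transverse displacement of the trapped bead) and SUM (total
collected power, sensitive to axial motion).  A trapped bead undergoes
overdamped Brownian motion in the harmonic trap, so those channels carry a
class-specific statistical fingerprint: the one-sided position spectrum is
a Lorentzian

    S(f) = kB·T / (π²·γ·(f0² + f²)),      f0 = k / (2π·γ),      γ = 6π·η·a,

whose corner frequency f0 and amplitude depend on the bead's size (through
the Stokes drag γ) and material (through the trap stiffness k).  This
package — aimed at optical-trapping and lab-on-chip researchers — turns
that fingerprint into a classification pipeline and quantifies how much of
it survives when only a single photodetector (the SUM channel) is
available:

* **`trap_sim`** — seeded overdamped Langevin simulation of labelled
  multi-class QPD datasets (default roster: PS 3/4/8 µm, PMMA 3/8 µm, and
  an empty trap; 6 acquisitions per class, 120 s at 10 kHz);
* **`calibration`** — trap stiffness by the equipartition method
  (k = kB·T/var(x)) and by Lorentzian fitting of the block-averaged power
  spectrum (k = 2π·f0·γ), used to verify that the simulator's programmed
  physics is recoverable;
* **`features`** — 500 ms segments → per-channel FFT magnitudes (DC
  removed) → independent 2-component PCA per channel: 3×5000 samples
  become 6 features (2 in SUM-only mode);
* **`classify`** — random forest, RBF-SVM, KNN and MLP under signal-wise
  stratified 6-fold cross-validation (all segments of an acquisition stay
  on one side of every split), with inner signal-wise tuning, accumulated
  row-normalised confusion matrices, and a paired 3-channel vs SUM-only
  comparison;
* **`pipeline` / CLI** — YAML-configured end-to-end runs with one seed
  reproducing every stage bit-for-bit.

## Worked example

```python
import numpy as np
import qpdclass as q

# --- calibrate a simulated bead: programmed k = 1e-6 N/m -----------------
medium = q.MediumSpec()                          # water, 298 K
drag = q.stokes_drag(1.5e-6, medium.viscosity)   # 2.516e-08 kg/s
trap = q.TrapSpec(stiffness=(1e-6,) * 3, drag=drag)
traj = q.simulate_trajectory(trap, medium, q.SimConfig(duration=120.0, seed=42))
est = q.calibrate_axis(traj.positions[0], 10_000.0, drag, medium.temperature)
print(f"equipartition: {est.equipartition:.3e}  power-spectrum: {est.power_spectrum:.3e}")

# --- classify the default 6-class roster (shortened 10 s acquisitions) ---
cfg = q.default_config().model_copy(deep=True)
cfg.sim.duration_s = 10.0
traces = q.generate_dataset(
    cfg.particle_classes(), cfg.signals_per_class, cfg.stiffness_table(),
    cfg.detector_model(), cfg.medium_spec(), cfg.sim_config(),
    base_seed=q.stage_seed(1, "simulate"),
)
spectra = q.traces_to_spectra(traces, 0.5)
cmp = q.compare_channel_modes(spectra, q.default_classifier_specs(7),
                              seed=q.stage_seed(1, "benchmark"))
for fam, delta in cmp.accuracy_delta.items():
    print(f"{fam:14s} 3-channel {cmp.all_channels.families[fam].mean_accuracy:.3f}"
          f"  SUM-only {cmp.sum_only.families[fam].mean_accuracy:.3f}"
          f"  gain {delta:+.3f}")
```

Output:

```
equipartition: 1.037e-06  power-spectrum: 1.042e-06
random_forest  3-channel 0.801  SUM-only 0.436  gain +0.365
svm            3-channel 0.833  SUM-only 0.465  gain +0.368
knn            3-channel 0.775  SUM-only 0.433  gain +0.342
mlp            3-channel 0.818  SUM-only 0.474  gain +0.344
```

Both calibration routes recover the programmed stiffness (1e-6 N/m) to
within a few percent — the simulator's physics is self-consistent.  In the
benchmark, every classifier family does markedly better with the full
3-channel QPD information than with the SUM channel alone; the confusion
matrices (in the returned reports) show the SUM-only models still separate
sizes and always recognise the empty trap, but largely lose the ability to
tell materials apart at equal size — the discriminating corner-frequency
information lives in the transverse channels.

The same study runs from the shell:

```sh
qpdclass run --out results/run --seed 1            # full default config (120 s signals)
qpdclass simulate --out results/ds --seed 1        # or stage by stage
qpdclass calibrate --trace results/ds/trace_0000.csv --axis x
qpdclass featurize --in results/ds --out results/features.csv
qpdclass benchmark --features results/features.csv --out results/bench --seed 1
qpdclass report --in results/bench/report.json
```

## Layout

```
src/qpdclass/      trap_sim, calibration, features, classify, io, pipeline, cli
src/qpdclass/data/ default.yaml — the committed default study configuration
docs/methods.md    model, estimators, protocol, design choices, limitations
tests/             unit, property and end-to-end acceptance tests
scripts/           acceptance.py
```
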