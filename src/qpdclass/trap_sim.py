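"""Synthetic quadrant-photodetector (QPD) datasets for optically trapped beads.

An optically trapped microsphere in water undergoes overdamped Brownian
motion in an effectively harmonic potential.  In the low-Reynolds-number
limit the inertial term of the Langevin equation is negligible and each
axis follows an independent Ornstein–Uhlenbeck process

    dx = -(k_i / gamma) x dt + sqrt(2 kB T / gamma) dW,

where ``k_i`` is the per-axis trap stiffness and ``gamma = 6 pi eta a`` the
Stokes drag of a sphere of radius ``a`` in a fluid of viscosity ``eta``.
This module integrates that process, renders the trajectories through a
simple linear detector model into (X, Y, SUM) voltage channels, and
assembles labelled multi-signal datasets that mimic a benchtop acquisition
campaign (several repeat acquisitions per particle class, plus an empty-trap
"no particle" class that contains detector noise only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "BOLTZMANN_CONSTANT",
    "ParticleClass",
    "MediumSpec",
    "TrapSpec",
    "DetectorModel",
    "SimConfig",
    "Trajectory",
    "QPDTrace",
    "stokes_drag",
    "corner_frequency",
    "class_to_trap",
    "simulate_trajectory",
    "render_qpd",
    "generate_dataset",
    "default_particle_classes",
    "default_stiffness_table",
    "trace_seed",
]

#: CODATA value of the Boltzmann constant, J/K.
BOLTZMANN_CONSTANT = 1.380649e-23

NO_PARTICLE_MATERIAL = "NONE"


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (e.g. negative radius)."""


class ConfigurationError(KeyError):
    """A required configuration entry is missing or inconsistent."""


class IntegratorStabilityError(RuntimeError):
    """The Euler–Maruyama step is unstable for the requested time step."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticleClass:
    """One species in the classification problem.

    ``radius`` is the sphere radius in metres (half the nominal diameter a
    vendor would quote).  ``material == "NONE"`` denotes the empty-trap
    class; it carries no physical particle, so radius and refractive index
    are unconstrained placeholders.
    """

    label: str
    material: str
    radius: float
    refractive_index: float

    def __post_init__(self) -> None:
        if self.material != NO_PARTICLE_MATERIAL:
            if self.radius <= 0:
                raise InvalidParameterError(
                    f"class {self.label!r}: radius must be > 0, got {self.radius}"
                )
            if self.refractive_index <= 1:
                raise InvalidParameterError(
                    f"class {self.label!r}: refractive index must exceed 1"
                )

    @property
    def is_empty_trap(self) -> bool:
        return self.material == NO_PARTICLE_MATERIAL


@dataclass(frozen=True)
class MediumSpec:
    """Immersion medium: temperature (K), dynamic viscosity (Pa s),
    refractive index at the trapping wavelength, and Boltzmann constant."""

    temperature: float = 298.0
    viscosity: float = 8.9e-4
    refractive_index: float = 1.3270
    boltzmann_constant: float = BOLTZMANN_CONSTANT

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise InvalidParameterError("temperature must be >= 0 K")
        if self.viscosity <= 0:
            raise InvalidParameterError("viscosity must be > 0")


@dataclass(frozen=True)
class TrapSpec:
    """Per-axis trap stiffness (N/m, diagonal: x, y, z) and Stokes drag (kg/s).

    ``stiffness == (0, 0, 0)`` together with ``drag == 0`` is the sentinel
    for the empty-trap class.
    """

    stiffness: tuple[float, float, float]
    drag: float

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.stiffness) or self.drag < 0:
            raise InvalidParameterError("stiffness and drag must be non-negative")
        trapped = any(k > 0 for k in self.stiffness)
        if trapped and self.drag <= 0:
            raise InvalidParameterError("a trapped particle requires drag > 0")

    @property
    def is_empty(self) -> bool:
        return all(k == 0 for k in self.stiffness)


@dataclass(frozen=True)
class DetectorModel:
    """Linear QPD transfer model.

    X and Y report transverse displacement scaled by ``xy_responsivity``
    (V/m); SUM reports total collected power, modelled as a baseline plus an
    axial-displacement term; every channel carries additive white Gaussian
    noise of standard deviation ``noise_sd`` volts per sample.
    """

    xy_responsivity: float = 1.0e7
    sum_baseline: float = 5.0
    sum_responsivity: float = 2.0e6
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.xy_responsivity < 0 or self.sum_responsivity < 0:
            raise InvalidParameterError("responsivities must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Time grid of the acquisition: sampling rate (Hz), duration (s),
    Euler–Maruyama sub-steps per output sample, burn-in discarded before
    recording (s), and the RNG seed."""

    sampling_rate: float = 10_000.0
    duration: float = 120.0
    integrator_substeps: int = 1
    burn_in: float = 1.0
    seed: int = 0
    integrator: Literal["euler", "exact"] = "euler"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise InvalidParameterError("sampling_rate and duration must be > 0")
        if self.integrator_substeps < 1:
            raise InvalidParameterError("integrator_substeps must be >= 1")
        if self.burn_in < 0:
            raise InvalidParameterError("burn_in must be >= 0")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sampling_rate)


@dataclass(frozen=True)
class Trajectory:
    """Particle position r(t): three equal-length axes in metres."""

    positions: np.ndarray  # shape (3, n)
    sampling_rate: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[0] != 3:
            raise InvalidParameterError("positions must have shape (3, n)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_samples(self) -> int:
        return self.positions.shape[1]


CHANNEL_NAMES = ("X", "Y", "SUM")


@dataclass(frozen=True)
class QPDTrace:
    """A labelled 3-channel (X, Y, SUM) voltage acquisition."""

    channels: np.ndarray  # shape (3, n), rows ordered X, Y, SUM
    sampling_rate: float
    label: str
    signal_id: int
    seed: int = 0

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 2 or ch.shape[0] != 3:
            raise InvalidParameterError("channels must have shape (3, n)")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        object.__setattr__(self, "channels", ch)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# Physics primitives
# ---------------------------------------------------------------------------


def stokes_drag(radius: float, viscosity: float) -> float:
    """Stokes drag coefficient ``gamma = 6 pi eta a`` of a sphere, kg/s."""
    if radius < 0:
        raise InvalidParameterError(f"radius must be >= 0, got {radius}")
    if viscosity <= 0:
        raise InvalidParameterError(f"viscosity must be > 0, got {viscosity}")
    return 6.0 * np.pi * viscosity * radius


def corner_frequency(stiffness_axis: float, drag: float) -> float:
    """Corner (roll-off) frequency ``f0 = k / (2 pi gamma)`` in Hz.

    Inverse of the stiffness–corner-frequency relation ``k = 2 pi f0 gamma``.
    """
    if drag <= 0:
        raise InvalidParameterError(f"drag must be > 0, got {drag}")
    if stiffness_axis < 0:
        raise InvalidParameterError("stiffness must be >= 0")
    return stiffness_axis / (2.0 * np.pi * drag)


# ---------------------------------------------------------------------------
# Default particle roster and trap configuration
# ---------------------------------------------------------------------------

# Refractive indices at 976 nm: polystyrene 1.5731, PMMA 1.4824.
_PS_INDEX = 1.5731
_PMMA_INDEX = 1.4824


def default_particle_classes() -> list[ParticleClass]:
    """The six-class roster: PS 3/4/8 um, PMMA 3/8 um, and an empty trap."""
    return [
        ParticleClass("ps3", "PS", 1.5e-6, _PS_INDEX),
        ParticleClass("ps4", "PS", 2.0e-6, _PS_INDEX),
        ParticleClass("ps8", "PS", 4.0e-6, _PS_INDEX),
        ParticleClass("pmma3", "PMMA", 1.5e-6, _PMMA_INDEX),
        ParticleClass("pmma8", "PMMA", 4.0e-6, _PMMA_INDEX),
        ParticleClass("none", NO_PARTICLE_MATERIAL, 0.0, 1.0),
    ]


def default_stiffness_table() -> dict[str, tuple[float, float, float]]:
    """Per-class trap stiffness defaults, N/m, axes (x, y, z).

    Chosen on physics grounds rather than fitted to any measurement: for a
    fixed laser power, stiffness grows with the particle/medium index
    contrast (PS > PMMA) and falls as the bead outgrows the focal spot
    (8 um < 4 um < 3 um here).  The axial (z) stiffness is 0.2x the
    transverse value, the usual order for a single-beam gradient trap.  The
    resulting corner frequencies place PS 3 um / PMMA 3 um / PS 4 um close
    together while the 8 um classes sit well apart.
    """
    table = {
        "ps3": 5.0e-6,
        "ps4": 4.5e-6,
        "ps8": 4.0e-6,
        "pmma3": 3.5e-6,
        "pmma8": 1.6e-6,
    }
    out = {label: (k, k, 0.2 * k) for label, k in table.items()}
    out["none"] = (0.0, 0.0, 0.0)
    return out


def class_to_trap(
    particle: ParticleClass,
    medium: MediumSpec,
    stiffness_table: Mapping[str, Sequence[float]],
) -> TrapSpec:
    """Resolve a particle class to its trap parameters.

    Drag comes from Stokes' law; stiffness is looked up per class label.
    The empty-trap class maps to the all-zero sentinel.
    """
    if particle.is_empty_trap:
        return TrapSpec(stiffness=(0.0, 0.0, 0.0), drag=0.0)
    if particle.label not in stiffness_table:
        raise ConfigurationError(
            f"no stiffness entry for class {particle.label!r}; "
            f"known labels: {sorted(stiffness_table)}"
        )
    kx, ky, kz = (float(v) for v in stiffness_table[particle.label])
    drag = stokes_drag(particle.radius, medium.viscosity)
    return TrapSpec(stiffness=(kx, ky, kz), drag=drag)


# ---------------------------------------------------------------------------
# Langevin integration
# ---------------------------------------------------------------------------


def _ou_axis(
    stiffness: float,
    drag: float,
    medium: MediumSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integrate one axis of the overdamped Langevin equation.

    Both integrators reduce to an AR(1) recursion x[n] = c x[n-1] + s w[n]
    with i.i.d. standard-normal w, evaluated with a vectorised IIR filter.
    Euler–Maruyama: c = 1 - theta dt, s = sqrt(2 D dt).  Exact OU update:
    c = exp(-theta dt), s = sqrt(var_inf (1 - c^2)).
    """
    dt = 1.0 / (config.sampling_rate * config.integrator_substeps)
    theta = stiffness / drag  # relaxation rate, 1/s
    if config.integrator == "euler" and theta * dt >= 2.0:
        raise IntegratorStabilityError(
            f"Euler-Maruyama unstable: k*dt/gamma = {theta * dt:.3g} >= 2; "
            "increase integrator_substeps"
        )
    kbt = medium.boltzmann_constant * medium.temperature
    n_burn = round(config.burn_in * config.sampling_rate) * config.integrator_substeps
    n_total = config.n_samples * config.integrator_substeps + n_burn

    if config.integrator == "exact":
        coef = np.exp(-theta * dt)
        if stiffness > 0:
            step_sd = np.sqrt((kbt / stiffness) * (1.0 - coef**2))
        else:
            step_sd = np.sqrt(2.0 * (kbt / drag) * dt)
    else:
        coef = 1.0 - theta * dt
        step_sd = np.sqrt(2.0 * (kbt / drag) * dt)

    noise = rng.standard_normal(n_total)
    x = lfilter([step_sd], [1.0, -coef], noise)
    # keep the recorded grid: drop burn-in, then every substeps-th point
    x = x[n_burn + config.integrator_substeps - 1 :: config.integrator_substeps]
    return x[: config.n_samples]


def simulate_trajectory(
    trap: TrapSpec, medium: MediumSpec, config: SimConfig
) -> Trajectory:
    """Simulate the 3-D position of a trapped bead on the recorded time grid.

    Axes are statistically independent (diagonal stiffness).  Deterministic
    for a fixed ``config.seed``; at zero temperature the thermal forcing
    vanishes and the trajectory is identically zero.
    """
    if trap.drag <= 0:
        raise InvalidParameterError("simulate_trajectory requires drag > 0")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    axes = [
        _ou_axis(k, trap.drag, medium, config, rng) for k in trap.stiffness
    ]
    return Trajectory(positions=np.vstack(axes), sampling_rate=config.sampling_rate)


def render_qpd(
    trajectory: Trajectory,
    detector: DetectorModel,
    rng_seed: int,
    *,
    label: str = "",
    signal_id: int = 0,
) -> QPDTrace:
    """Render a trajectory into (X, Y, SUM) detector voltages with noise."""
    if trajectory.n_samples == 0:
        raise InvalidParameterError("trajectory is empty")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    x, y, z = trajectory.positions
    n = trajectory.n_samples
    noise = detector.noise_sd * rng.standard_normal((3, n))
    channels = np.vstack(
        [
            detector.xy_responsivity * x + noise[0],
            detector.xy_responsivity * y + noise[1],
            detector.sum_baseline + detector.sum_responsivity * z + noise[2],
        ]
    )
    return QPDTrace(
        channels=channels,
        sampling_rate=trajectory.sampling_rate,
        label=label,
        signal_id=signal_id,
        seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def trace_seed(base_seed: int, class_index: int, signal_index: int, stream: int) -> int:
    """Derive a per-trace seed: hash of (base_seed, class, signal, stream).

    Pure function via numpy's SeedSequence spawn-key mechanism; ``stream`` 0
    feeds the Langevin integrator, 1 the detector noise.
    """
    ss = np.random.SeedSequence(base_seed, spawn_key=(class_index, signal_index, stream))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_dataset(
    classes: Sequence[ParticleClass],
    signals_per_class: int,
    stiffness_table: Mapping[str, Sequence[float]],
    detector: DetectorModel,
    medium: MediumSpec,
    sim_config: SimConfig,
    base_seed: int,
) -> list[QPDTrace]:
    """Simulate ``len(classes) x signals_per_class`` labelled acquisitions.

    Mirrors a campaign of repeat acquisitions per bead type.  Each trace
    gets an independent seed derived from (base_seed, class index, signal
    index), so the whole dataset is reproducible from ``base_seed`` alone.
    Empty-trap traces skip the Langevin step: the detector sees a still
    focal volume, i.e. baseline plus noise.
    """
    if not classes:
        raise InvalidParameterError("class list is empty")
    if signals_per_class < 1:
        raise InvalidParameterError("signals_per_class must be >= 1")
    traces: list[QPDTrace] = []
    signal_id = 0
    for ci, particle in enumerate(classes):
        trap = class_to_trap(particle, medium, stiffness_table)
        for si in range(signals_per_class):
            sim_seed = trace_seed(base_seed, ci, si, 0)
            det_seed = trace_seed(base_seed, ci, si, 1)
            if trap.is_empty:
                traj = Trajectory(
                    positions=np.zeros((3, sim_config.n_samples)),
                    sampling_rate=sim_config.sampling_rate,
                )
            else:
                traj = simulate_trajectory(
                    trap, medium, replace(sim_config, seed=sim_seed)
                )
            traces.append(
                render_qpd(
                    traj,
                    detector,
                    det_seed,
                    label=particle.label,
                    signal_id=signal_id,
                )
            )
            signal_id += 1
    return traces
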