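import numpy as np
import pytest

from qpdclass import (
    DetectorModel,
    MediumSpec,
    QPDTrace,
    SimConfig,
    TrapSpec,
    default_particle_classes,
    default_stiffness_table,
    stokes_drag,
)

KB = 1.380649e-23


@pytest.fixture(scope="session")
def medium() -> MediumSpec:
    return MediumSpec()


@pytest.fixture(scope="session")
def detector() -> DetectorModel:
    return DetectorModel()


@pytest.fixture(scope="session")
def reference_trap(medium) -> TrapSpec:
    """The calibration reference: k = 1e-6 N/m on every axis, 1.5 um bead."""
    drag = stokes_drag(1.5e-6, medium.viscosity)
    return TrapSpec(stiffness=(1e-6, 1e-6, 1e-6), drag=drag)


@pytest.fixture(scope="session")
def long_sim_config() -> SimConfig:
    """Full-length acquisition grid: 120 s at 10 kHz."""
    return SimConfig(sampling_rate=10_000.0, duration=120.0, seed=42)


def make_noise_trace(
    n: int = 5000, seed: int = 0, sampling_rate: float = 10_000.0,
    label: str = "none", signal_id: int = 0,
) -> QPDTrace:
    rng = np.random.default_rng(seed)
    return QPDTrace(
        channels=rng.standard_normal((3, n)),
        sampling_rate=sampling_rate,
        label=label,
        signal_id=signal_id,
    )


@pytest.fixture
def noise_trace() -> QPDTrace:
    return make_noise_trace()


@pytest.fixture(scope="session")
def roster():
    return default_particle_classes()


@pytest.fixture(scope="session")
def stiffness_table():
    return default_stiffness_table()
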