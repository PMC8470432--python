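"""Unit and property tests for the Langevin simulator and detector model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpdclass import (
    DetectorModel,
    MediumSpec,
    ParticleClass,
    SimConfig,
    Trajectory,
    TrapSpec,
    class_to_trap,
    corner_frequency,
    generate_dataset,
    render_qpd,
    simulate_trajectory,
    stokes_drag,
)
from qpdclass.trap_sim import (
    ConfigurationError,
    IntegratorStabilityError,
    InvalidParameterError,
    trace_seed,
)

from conftest import KB


class TestStokesDrag:
    def test_direct_evaluation(self):
        # gamma = 6 pi eta a for a 1.5 um bead in water
        assert stokes_drag(1.5e-6, 8.9e-4) == pytest.approx(
            6 * np.pi * 8.9e-4 * 1.5e-6, rel=1e-12
        )

    def test_zero_radius(self):
        assert stokes_drag(0.0, 8.9e-4) == 0.0

    def test_linearity_in_radius(self):
        assert stokes_drag(3e-6, 1e-3) == pytest.approx(2 * stokes_drag(1.5e-6, 1e-3))

    @pytest.mark.parametrize("radius,viscosity", [(-1e-6, 1e-3), (1e-6, 0.0), (1e-6, -1.0)])
    def test_invalid_parameters(self, radius, viscosity):
        with pytest.raises(InvalidParameterError):
            stokes_drag(radius, viscosity)

    @given(
        a=st.floats(1e-8, 1e-4), da=st.floats(1e-8, 1e-4),
        eta=st.floats(1e-5, 1e-1), deta=st.floats(1e-5, 1e-1),
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing(self, a, da, eta, deta):
        assert stokes_drag(a + da, eta) > stokes_drag(a, eta)
        assert stokes_drag(a, eta + deta) > stokes_drag(a, eta)


class TestCornerFrequency:
    def test_hand_value(self):
        assert corner_frequency(1e-6, 2.5e-8) == pytest.approx(
            1e-6 / (2 * np.pi * 2.5e-8), rel=1e-12
        )

    def test_zero_stiffness(self):
        assert corner_frequency(0.0, 2.5e-8) == 0.0

    def test_round_trip_with_stiffness_relation(self):
        gamma = 2.5e-8
        f0 = corner_frequency(3.7e-6, gamma)
        assert 2 * np.pi * f0 * gamma == pytest.approx(3.7e-6, rel=1e-14)

    def test_nonpositive_drag_rejected(self):
        with pytest.raises(InvalidParameterError):
            corner_frequency(1e-6, 0.0)


class TestClassToTrap:
    def test_empty_trap_is_all_zero(self, medium, stiffness_table):
        none = ParticleClass("none", "NONE", 0.0, 1.0)
        trap = class_to_trap(none, medium, stiffness_table)
        assert trap.stiffness == (0.0, 0.0, 0.0) and trap.drag == 0.0

    def test_lookup_and_stokes_drag(self, medium):
        ps3 = ParticleClass("ps3", "PS", 1.5e-6, 1.5731)
        table = {"ps3": (2e-6, 2e-6, 4e-7)}
        trap = class_to_trap(ps3, medium, table)
        assert trap.stiffness == (2e-6, 2e-6, 4e-7)
        assert trap.drag == pytest.approx(stokes_drag(1.5e-6, medium.viscosity))

    def test_shared_entry_different_drag(self, medium):
        table = {"a": (1e-6, 1e-6, 2e-7), "b": (1e-6, 1e-6, 2e-7)}
        trap_a = class_to_trap(ParticleClass("a", "PS", 1e-6, 1.57), medium, table)
        trap_b = class_to_trap(ParticleClass("b", "PS", 2e-6, 1.57), medium, table)
        assert trap_a.stiffness == trap_b.stiffness
        assert trap_b.drag == pytest.approx(2 * trap_a.drag)

    def test_missing_label_names_class(self, medium):
        ps3 = ParticleClass("ps3", "PS", 1.5e-6, 1.5731)
        with pytest.raises(ConfigurationError, match="ps3"):
            class_to_trap(ps3, medium, {})


class TestSimulateTrajectory:
    def test_zero_temperature_freezes_particle(self, reference_trap):
        cold = MediumSpec(temperature=0.0)
        traj = simulate_trajectory(reference_trap, cold, SimConfig(duration=0.5, seed=1))
        assert np.all(traj.positions == 0.0)

    def test_seed_determinism(self, reference_trap, medium):
        cfg = SimConfig(duration=1.0, seed=5)
        a = simulate_trajectory(reference_trap, medium, cfg)
        b = simulate_trajectory(reference_trap, medium, cfg)
        assert np.array_equal(a.positions, b.positions)

    def test_equipartition_variance(self, reference_trap, medium, long_sim_config):
        """Stationary variance approaches kB T / k on a 120 s trace."""
        traj = simulate_trajectory(reference_trap, medium, long_sim_config)
        expected = KB * medium.temperature / reference_trap.stiffness[0]
        assert np.var(traj.positions[0]) == pytest.approx(expected, rel=0.05)

    def test_autocovariance_decay_rate(self, reference_trap, medium):
        """Autocorrelation decays as exp(-(k/gamma) tau); fitted rate within 10%."""
        cfg = SimConfig(duration=60.0, seed=11)
        traj = simulate_trajectory(reference_trap, medium, cfg)
        x = traj.positions[0] - traj.positions[0].mean()
        theta = reference_trap.stiffness[0] / reference_trap.drag
        dt = 1.0 / cfg.sampling_rate
        max_lag = int(0.5 / (theta * dt))  # up to half a relaxation time
        lags = np.arange(1, max_lag)
        acf = np.array([np.mean(x[: -l] * x[l:]) for l in lags]) / np.var(x)
        slope = np.polyfit(lags * dt, np.log(acf), 1)[0]
        assert -slope == pytest.approx(theta, rel=0.10)

    def test_substep_invariance_of_variance(self, reference_trap, medium):
        cfgs = [SimConfig(duration=30.0, seed=3, integrator_substeps=s) for s in (1, 10)]
        variances = [
            np.var(simulate_trajectory(reference_trap, medium, c).positions[0])
            for c in cfgs
        ]
        # Monte-Carlo scatter of a 30 s variance estimate is a few percent
        assert variances[0] == pytest.approx(variances[1], rel=0.10)

    def test_exact_ou_integrator_agrees(self, reference_trap, medium):
        var = {}
        for integ in ("euler", "exact"):
            cfg = SimConfig(duration=30.0, seed=9, integrator=integ)
            var[integ] = np.var(simulate_trajectory(reference_trap, medium, cfg).positions[0])
        assert var["euler"] == pytest.approx(var["exact"], rel=0.10)

    def test_unstable_step_raises(self, medium):
        trap = TrapSpec(stiffness=(1e-6,) * 3, drag=1e-9)  # theta = 1000 / s
        cfg = SimConfig(sampling_rate=100.0, duration=1.0)  # theta*dt = 10
        with pytest.raises(IntegratorStabilityError, match="integrator_substeps"):
            simulate_trajectory(trap, medium, cfg)

    def test_output_length(self, reference_trap, medium):
        cfg = SimConfig(duration=1.7, sampling_rate=1000.0, seed=0)
        traj = simulate_trajectory(reference_trap, medium, cfg)
        assert traj.n_samples == 1700


class TestRenderQPD:
    def test_zero_trajectory_zero_noise(self):
        det = DetectorModel(noise_sd=0.0)
        traj = Trajectory(positions=np.zeros((3, 100)), sampling_rate=1e4)
        trace = render_qpd(traj, det, rng_seed=0)
        assert np.all(trace.channels[0] == 0.0)
        assert np.all(trace.channels[1] == 0.0)
        assert np.all(trace.channels[2] == det.sum_baseline)

    def test_noiseless_x_is_affine_image(self, detector):
        rng = np.random.default_rng(2)
        pos = rng.standard_normal((3, 1000)) * 1e-8
        det = DetectorModel(noise_sd=0.0)
        trace = render_qpd(Trajectory(pos, 1e4), det, rng_seed=0)
        assert np.corrcoef(trace.channels[0], pos[0])[0, 1] == pytest.approx(1.0)

    def test_noise_only_sd(self):
        """Empty-trap channels are white noise of the configured SD."""
        det = DetectorModel(noise_sd=0.01)
        traj = Trajectory(positions=np.zeros((3, 200_000)), sampling_rate=1e4)
        trace = render_qpd(traj, det, rng_seed=7)
        for c in range(3):
            assert np.std(trace.channels[c]) == pytest.approx(0.01, rel=0.03)


class TestGenerateDataset:
    @pytest.fixture(scope="class")
    def tiny_dataset(self, roster, stiffness_table, detector, medium):
        cfg = SimConfig(duration=0.5, burn_in=0.1)
        return generate_dataset(
            roster, 2, stiffness_table, detector, medium, cfg, base_seed=3
        )

    def test_trace_count_and_labels(self, tiny_dataset, roster):
        assert len(tiny_dataset) == len(roster) * 2
        labels = [t.label for t in tiny_dataset]
        for cls in roster:
            assert labels.count(cls.label) == 2

    def test_signal_ids_unique(self, tiny_dataset):
        ids = [t.signal_id for t in tiny_dataset]
        assert len(set(ids)) == len(ids)

    def test_base_seed_reproducibility(self, tiny_dataset, roster, stiffness_table,
                                       detector, medium):
        cfg = SimConfig(duration=0.5, burn_in=0.1)
        again = generate_dataset(
            roster, 2, stiffness_table, detector, medium, cfg, base_seed=3
        )
        for a, b in zip(tiny_dataset, again):
            assert np.array_equal(a.channels, b.channels)

    def test_empty_class_list_rejected(self, stiffness_table, detector, medium):
        with pytest.raises(InvalidParameterError):
            generate_dataset([], 2, stiffness_table, detector, medium, SimConfig(), 0)

    def test_trace_seed_is_pure_and_bounded(self):
        assert trace_seed(1, 2, 3, 0) == trace_seed(1, 2, 3, 0)
        assert trace_seed(1, 2, 3, 0) != trace_seed(1, 2, 3, 1)
        assert 0 <= trace_seed(123, 5, 5, 1) < 2**31
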