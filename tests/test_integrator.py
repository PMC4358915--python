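"""Langevin propagator tests: limits, thermostat, diffusion, determinism."""

import numpy as np
import pytest

import corralsim as cs
from corralsim.constants import (
    ACCEL_CONVERSION,
    diffusion_constant_A2_per_ps,
    thermal_energy,
)
from corralsim.integrator import run_replica


class TestLdStepLimits:
    def test_zero_friction_zero_force_is_uniform_motion(self, rng):
        """gamma=0, T=0, F=0: positions advance by v*dt exactly."""
        params = cs.IntegratorParams(friction=0.0, temperature=0.0, timestep=0.01)
        pos = rng.normal(size=(5, 3))
        vel = rng.normal(size=(5, 3))
        p, v, _ = cs.ld_step(pos, vel, lambda x: np.zeros_like(x), 1043.0, params, rng)
        assert np.allclose(p, pos + vel * 0.01, atol=1e-14)
        assert np.allclose(v, vel, atol=1e-14)

    def test_nonfinite_force_reported_with_particle(self, rng):
        params = cs.IntegratorParams()

        def bad_force(x):
            f = np.zeros_like(x)
            f[2, 0] = np.nan
            return f

        with pytest.raises(FloatingPointError, match="particle 2"):
            cs.ld_step(np.zeros((4, 3)), np.zeros((4, 3)), bad_force, 1043.0, params, rng)

    def test_microcanonical_energy_drift_is_small(self):
        """gamma=0 reduces to velocity Verlet: harmonic energy conserved."""
        k = 0.6
        m = 1043.0
        params = cs.IntegratorParams(friction=0.0, temperature=0.0, timestep=0.005)
        rng = np.random.default_rng(3)
        pos = np.array([[0.0, 0.0, 2.0]])
        vel = np.array([[0.0, 0.0, 0.3]])

        def force(x):
            f = np.zeros_like(x)
            f[:, 2] = -2.0 * k * x[:, 2]
            return f

        def energy(x, v):
            return k * x[0, 2] ** 2 + 0.5 * m * (v[0] ** 2).sum() / ACCEL_CONVERSION

        e0 = energy(pos, vel)
        f = force(pos)
        for _ in range(100_000):
            pos, vel, f = cs.ld_step(pos, vel, force, m, params, rng, forces=f)
        assert abs(energy(pos, vel) - e0) / e0 < 1e-4


class TestKernelDynamics:
    def test_identical_seeds_identical_trajectories(self, pip2, small_geometry):
        kw = dict(n_steps=200, snapshot_every=20, seed=42)
        params = cs.IntegratorParams(friction=1.0, timestep=0.005)
        pos = np.array([[-30.0, 0.0, 0.0], [-15.0, 5.0, 0.0], [-40.0, -10.0, 0.0]])
        t1 = run_replica(pos, pip2, small_geometry, params, **kw)
        t2 = run_replica(pos, pip2, small_geometry, params, **kw)
        assert np.array_equal(t1.positions, t2.positions)
        t3 = run_replica(pos, pip2, small_geometry, params, n_steps=200, snapshot_every=20, seed=43)
        assert not np.array_equal(t1.positions, t3.positions)

    def test_kernel_matches_reference_step_without_noise(self, pip2, small_geometry):
        """Deterministic limit: jitted BAOAB equals the python reference."""
        params = cs.IntegratorParams(friction=0.0, temperature=0.0, timestep=0.005)
        pos0 = np.array([[-30.0, 0.0, 1.0], [-15.0, 5.0, -1.0]])
        vel0 = np.zeros((2, 3))
        traj = run_replica(
            pos0, pip2, small_geometry, params, n_steps=50, snapshot_every=50,
            seed=0, velocities=vel0,
        )
        pos, vel = pos0.copy(), vel0.copy()
        force = lambda x: cs.total_energy(x, pip2, small_geometry)[1]
        rng = np.random.default_rng(0)
        f = force(pos)
        for _ in range(50):
            pos, vel, f = cs.ld_step(pos, vel, force, pip2.mass, params, rng, forces=f)
        assert np.allclose(traj.positions[-1], pos, atol=1e-10)

    def test_kinetic_temperature_thermostats_to_target(self, pip2, small_geometry):
        params = cs.IntegratorParams(friction=1.0, temperature=300.0, timestep=0.005)
        gx, gy = np.meshgrid(np.arange(-52, -10, 14.0), np.arange(-42, 42, 14.0))
        pos = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        traj = run_replica(
            pos, pip2, small_geometry, params, n_steps=20_000, snapshot_every=100, seed=9,
        )
        temp = cs.kinetic_temperature(traj, pip2.mass)
        assert temp == pytest.approx(300.0, rel=0.05)

    def test_kinetic_temperature_of_static_system_is_zero(self):
        traj = cs.Trajectory(
            times=np.array([0.0]), positions=np.zeros((1, 4, 3)),
            velocities=np.zeros((1, 4, 3)),
        )
        assert cs.kinetic_temperature(traj, 1043.0) == 0.0

    def test_harmonic_plane_variance_satisfies_equipartition(self, pip2, small_geometry):
        """U = k z^2 (no 1/2): equilibrium variance is kT/(2k)."""
        params = cs.IntegratorParams(friction=1.0, temperature=300.0, timestep=0.005)
        pos = np.column_stack([
            np.linspace(-45, -15, 24), np.linspace(-35, 35, 24), np.zeros(24)
        ])
        traj = run_replica(
            pos, pip2, small_geometry, params, n_steps=40_000, snapshot_every=50,
            seed=11, pair_interactions=False,
        )
        var = traj.positions[100:, :, 2].var()
        expected = thermal_energy(300.0) / (2 * small_geometry.planar_force_constant)
        assert var == pytest.approx(expected, rel=0.1)

    def test_free_diffusion_msd_recovers_einstein_relation(self, pip2, small_geometry):
        """In-plane MSD slope/4 = k_B T/(m gamma) for free particles."""
        gamma = 1.0
        params = cs.IntegratorParams(friction=gamma, temperature=300.0, timestep=0.005)
        pos = np.zeros((400, 3))
        traj = run_replica(
            pos, pip2, small_geometry, params, n_steps=40_000, snapshot_every=200,
            seed=5, pair_interactions=False, walls=False,
        )
        d = cs.msd_diffusion(traj, fit_window=(20.0, 160.0), friction=gamma)
        d_expected = diffusion_constant_A2_per_ps(300.0, pip2.mass, gamma) * 1e-4
        assert d == pytest.approx(d_expected, rel=0.1)


class TestProtocol:
    def test_zero_production_returns_single_frame(self, pip2, small_geometry):
        params = cs.IntegratorParams(friction=1.0, timestep=0.01, seed=7)
        protocol = cs.SimulationProtocol(
            equilibration_time=1.0, production_time=0.0, n_replicas=2,
            snapshot_interval=1.0,
        )
        pos = np.array([[-30.0, 0.0, 0.0], [-20.0, 10.0, 0.0]])
        trajs = cs.run_protocol(pos, pip2, small_geometry, params, protocol)
        assert len(trajs) == 2
        assert all(t.n_frames == 1 for t in trajs)

    def test_equilibration_confines_to_corral(self, pip2, small_geometry):
        """With the corral wall on, no particle ends equilibration far past x=0."""
        params = cs.IntegratorParams(friction=0.1, timestep=0.01, seed=21)
        protocol = cs.SimulationProtocol(
            equilibration_time=500.0, production_time=50.0, n_replicas=1,
            snapshot_interval=25.0,
        )
        pos = np.column_stack([
            np.linspace(-50, -5, 10), np.linspace(-40, 40, 10), np.zeros(10)
        ])
        trajs = cs.run_protocol(pos, pip2, small_geometry, params, protocol)
        first = trajs[0].positions[0]
        assert np.all(first[:, 0] < 2.0)  # small wall penetration at most

    def test_replicas_use_distinct_seeds(self, pip2, small_geometry):
        params = cs.IntegratorParams(friction=1.0, timestep=0.01, seed=3)
        protocol = cs.SimulationProtocol(
            equilibration_time=0.0, production_time=10.0, n_replicas=3,
            snapshot_interval=1.0,
        )
        pos = np.array([[-30.0, 0.0, 0.0]])
        trajs = cs.run_protocol(pos, pip2, small_geometry, params, protocol)
        finals = [t.positions[-1] for t in trajs]
        assert not np.allclose(finals[0], finals[1])
        assert not np.allclose(finals[1], finals[2])
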