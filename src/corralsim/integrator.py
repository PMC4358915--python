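"""Langevin dynamics propagation and the equilibration/production protocol.

The propagator is the BAOAB splitting of the Langevin equation: a
velocity half-kick (B), a half drift (A), an exact Ornstein-Uhlenbeck
update of the velocities (O), then A and B again.  With friction set to
zero it reduces to velocity Verlet.  The reference protocol equilibrates
the pool with a one-sided harmonic wall holding every sphere inside the
corral (x < corral boundary), then removes the wall and records
snapshots over the production span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _kernels
from .constants import ACCEL_CONVERSION, BOLTZMANN_KCAL, debye_kappa, thermal_energy
from .fences import FenceAtoms
from .grids import GridPotential
from .model_core import ParticleSpec, SystemGeometry

__all__ = [
    "IntegratorParams",
    "SimulationProtocol",
    "Trajectory",
    "ld_step",
    "run_replica",
    "run_protocol",
    "kinetic_temperature",
]

_EMPTY_GRID = np.zeros((3, 3, 3))
_EMPTY_META = np.zeros(6)


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin parameters: friction (1/ps), temperature (K), timestep (ps)."""

    friction: float = 1.0
    temperature: float = 300.0
    timestep: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")


@dataclass(frozen=True)
class SimulationProtocol:
    """Equilibration/production schedule (times in ps).

    The reference protocol equilibrates for 25 ns with the corral
    constraint on, then runs 10 us of unconstrained production; 20
    replicas for rod-like fences and 30 for protein fences.
    """

    equilibration_time: float = 25_000.0
    production_time: float = 1.0e7
    n_replicas: int = 20
    snapshot_interval: float = 1000.0

    def __post_init__(self) -> None:
        if self.equilibration_time < 0 or self.production_time < 0:
            raise ValueError("times must be non-negative")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot interval must be positive")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")


@dataclass
class Trajectory:
    """Snapshots of one replica: times (ps) and positions (F, N, 3) A."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self):
        """Long-form columnar view: replica, time, particle, x, y, z."""
        import pandas as pd

        f, n, _ = self.positions.shape
        rep = self.metadata.get("replica", 0)
        return pd.DataFrame(
            {
                "replica": np.full(f * n, rep, dtype=int),
                "time": np.repeat(self.times, n),
                "particle": np.tile(np.arange(n), f),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "z": self.positions[:, :, 2].ravel(),
            }
        )


def ld_step(
    positions: np.ndarray,
    velocities: np.ndarray,
    force_fn: Callable[[np.ndarray], np.ndarray],
    mass: float,
    params: IntegratorParams,
    rng: np.random.Generator,
    forces: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One BAOAB step (reference implementation, any force callable).

    Returns (positions, velocities, forces-at-new-positions).  With
    friction 0 and temperature 0 this is exactly velocity Verlet.
    """
    pos = np.array(positions, dtype=float)
    vel = np.array(velocities, dtype=float)
    if forces is None:
        forces = force_fn(pos)
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.isfinite(forces).all(axis=-1))[0, 0])
        raise FloatingPointError(f"non-finite force on particle {bad}")
    dt = params.timestep
    accel = ACCEL_CONVERSION / mass
    vel = vel + 0.5 * dt * forces * accel
    pos = pos + 0.5 * dt * vel
    if params.friction > 0:
        c1 = np.exp(-params.friction * dt)
        sigma = np.sqrt(
            thermal_energy(params.temperature) * ACCEL_CONVERSION / mass * (1 - c1**2)
        )
        vel = c1 * vel + sigma * rng.standard_normal(vel.shape)
    pos = pos + 0.5 * dt * vel
    new_forces = force_fn(pos)
    vel = vel + 0.5 * dt * new_forces * accel
    return pos, vel, new_forces


def _grid_args(grid: GridPotential | None):
    if grid is None:
        return False, _EMPTY_GRID, _EMPTY_META
    meta = np.concatenate([grid.origin, grid.spacing])
    return True, np.ascontiguousarray(grid.values), meta


def run_replica(
    positions: np.ndarray,
    particle: ParticleSpec,
    geometry: SystemGeometry,
    params: IntegratorParams,
    n_steps: int,
    snapshot_every: int,
    seed: int,
    fence: FenceAtoms | None = None,
    core_grid: GridPotential | None = None,
    phix_grid: GridPotential | None = None,
    fence_kappa: float | None = None,
    corral_constraint: bool = False,
    walls: bool = True,
    pair_interactions: bool = True,
    pair_cutoff: float | None = None,
    external_gaussian: tuple[float, float, float] | None = None,
    velocities: np.ndarray | None = None,
    record_velocities: bool = True,
) -> Trajectory:
    """Propagate one replica with the jitted BAOAB kernel.

    ``external_gaussian`` imposes an extra 1D potential
    amp*exp(-(x-x0)^2/(2 sigma^2)) -- used for Boltzmann-inversion QC.
    ``fence_kappa`` is the inverse screening length (1/A) applied to
    fence-sphere charges (default: 150 mM / eps 80 / 300 K).
    ``pair_cutoff`` switches on energy-shifted truncation of pair and
    fence interactions at the given radius (A) -- intended only for the
    scaled-down test profile; the reference model uses none.
    """
    pos = np.array(positions, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    rng = np.random.default_rng(seed)
    if velocities is None:
        sigma_v = np.sqrt(
            thermal_energy(params.temperature) * ACCEL_CONVERSION / particle.mass
        )
        vel = sigma_v * rng.standard_normal((n, 3))
    else:
        vel = np.array(velocities, dtype=float).reshape(-1, 3)

    if fence is None or fence.n_atoms == 0:
        fence_pos = np.zeros((0, 3))
        fence_q = np.zeros(0)
        fence_rmin = np.zeros(0)
        fence_lj = False
    else:
        fence_pos = np.ascontiguousarray(fence.coords)
        fence_q = np.ascontiguousarray(fence.charges)
        fence_rmin = np.ascontiguousarray(fence.radii + particle.lj_rmin_half)
        fence_lj = bool(fence.steric)
    if fence_kappa is None:
        fence_kappa = debye_kappa(0.150, 80.0, params.temperature or 300.0)

    if external_gaussian is None:
        ext_amp, ext_x0, ext_sigma = 0.0, 0.0, 1.0
    else:
        ext_amp, ext_x0, ext_sigma = external_gaussian

    use_core, core_vals, core_meta = _grid_args(core_grid)
    use_phix, phix_vals, phix_meta = _grid_args(phix_grid)

    from .constants import COULOMB_CONSTANT, PAIR_DIELECTRIC

    if pair_cutoff is None:
        pair_rc2, pair_shift = 0.0, 0.0
        fence_rc2 = 0.0
        fence_shift = np.zeros(len(fence_pos))
    else:
        rc = float(pair_cutoff)
        pair_rc2 = rc * rc
        rc6 = (2.0 * particle.lj_rmin_half / rc) ** 6
        qqfac = COULOMB_CONSTANT * particle.charge**2 / PAIR_DIELECTRIC
        pair_shift = particle.lj_well_depth * (rc6**2 - 2.0 * rc6) + qqfac / rc
        fence_rc2 = rc * rc
        fence_shift = np.zeros(len(fence_pos))
        for k in range(len(fence_pos)):
            if fence_lj:
                rk6 = (fence_rmin[k] / rc) ** 6
                fence_shift[k] += particle.lj_well_depth * (rk6**2 - 2.0 * rk6)
            if fence_q[k] != 0.0:
                pref = COULOMB_CONSTANT * particle.charge * fence_q[k] / PAIR_DIELECTRIC
                fence_shift[k] += pref * np.exp(-fence_kappa * rc) / rc

    n_frames = 1 + (n_steps // snapshot_every if snapshot_every > 0 else 0)
    out_pos = np.zeros((n_frames, n, 3))
    out_vel = np.zeros((n_frames, n, 3))

    kernel_seed = int(seed) % (2**31 - 1)
    nframes = _kernels.ld_run(
        pos,
        vel,
        n_steps,
        params.timestep,
        params.friction,
        thermal_energy(params.temperature),
        particle.mass,
        particle.charge,
        particle.lj_well_depth,
        2.0 * particle.lj_rmin_half,
        pair_interactions,
        pair_rc2,
        pair_shift,
        fence_pos,
        fence_q,
        fence_lj,
        fence_rmin,
        particle.lj_well_depth,
        fence_kappa,
        fence_rc2,
        fence_shift,
        geometry.planar_force_constant,
        geometry.diffusion_plane_z,
        geometry.wall_force_constant,
        geometry.box_x_lo,
        geometry.box_x_hi,
        geometry.box_y_lo,
        geometry.box_y_hi,
        walls,
        geometry.corral_boundary_x,
        corral_constraint,
        ext_amp,
        ext_x0,
        ext_sigma,
        use_core,
        core_vals,
        core_meta,
        use_phix,
        phix_vals,
        phix_meta,
        snapshot_every,
        kernel_seed,
        out_pos,
        out_vel,
    )
    if nframes < 0:
        raise FloatingPointError("integration instability: non-finite forces")
    times = params.timestep * snapshot_every * np.arange(nframes) if snapshot_every > 0 else np.zeros(1)
    return Trajectory(
        times=times,
        positions=out_pos[:nframes],
        velocities=out_vel[:nframes] if record_velocities else None,
        metadata={
            "scheme": "BAOAB",
            "seed": int(seed),
            "friction": params.friction,
            "temperature": params.temperature,
            "timestep": params.timestep,
            "final_positions": pos,
            "final_velocities": vel,
        },
    )


def run_protocol(
    initial_positions: np.ndarray,
    particle: ParticleSpec,
    geometry: SystemGeometry,
    params: IntegratorParams,
    protocol: SimulationProtocol,
    fence: FenceAtoms | None = None,
    core_grid: GridPotential | None = None,
    phix_grid: GridPotential | None = None,
    fence_kappa: float | None = None,
    pair_cutoff: float | None = None,
) -> list[Trajectory]:
    """Equilibrate-then-produce for every replica; deterministic per seed.

    Equilibration applies the one-sided corral wall (x < corral
    boundary) and discards snapshots; production removes it and records
    positions every ``snapshot_interval``.
    """
    seeds = np.random.SeedSequence(params.seed).generate_state(protocol.n_replicas)
    dt = params.timestep
    eq_steps = int(round(protocol.equilibration_time / dt))
    prod_steps = int(round(protocol.production_time / dt))
    snap_every = max(1, int(round(protocol.snapshot_interval / dt)))

    trajectories = []
    for rep, s in enumerate(seeds):
        eq = run_replica(
            initial_positions,
            particle,
            geometry,
            params,
            n_steps=eq_steps,
            snapshot_every=max(eq_steps, 1),
            seed=int(s),
            fence=fence,
            core_grid=core_grid,
            phix_grid=phix_grid,
            fence_kappa=fence_kappa,
            pair_cutoff=pair_cutoff,
            corral_constraint=True,
        )
        prod = run_replica(
            eq.metadata["final_positions"],
            particle,
            geometry,
            params,
            n_steps=prod_steps,
            snapshot_every=snap_every,
            seed=int(s) + 1,
            fence=fence,
            core_grid=core_grid,
            phix_grid=phix_grid,
            fence_kappa=fence_kappa,
            pair_cutoff=pair_cutoff,
            corral_constraint=False,
            velocities=eq.metadata["final_velocities"],
        )
        prod.metadata["replica"] = rep
        trajectories.append(prod)
    return trajectories


def kinetic_temperature(trajectory: Trajectory, mass: float) -> float:
    """Mean kinetic temperature (K) over a trajectory window."""
    if trajectory.velocities is None or trajectory.velocities.size == 0:
        raise ValueError("trajectory carries no velocities")
    v2 = (trajectory.velocities**2).sum(axis=-1)  # (F, N) in A^2/ps^2
    ke_kcal = 0.5 * mass * v2 / ACCEL_CONVERSION
    ndof = 3.0
    return float(2.0 * ke_kcal.mean() / (ndof * BOLTZMANN_KCAL))
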