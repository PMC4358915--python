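"""The physical model: PIP2-like spheres and every term of their energy.

A PIP2 molecule is reduced to a single sphere carrying its net headgroup
charge (-4e), confined near a diffusion plane 5 A above the lipid
phosphate plane.  The total energy of sphere i is

    U(r_i) = sum_j [ eps_ij ((rmin/r)^12 - 2 (rmin/r)^6) + k_e q_i q_j / (80 r) ]
             + U_CORE(r_i) + q_i * phi_PHIX(r_i)
             + k_plane (z_i - z_plane)^2 + wall terms,

where U_CORE and phi_PHIX are precomputed grid maps (steric exclusion and
implicit-membrane electrostatics of the fence).  Harmonic restraints use
the CHARMM convention U = k * delta^2 with no 1/2 prefactor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_CONSTANT, PAIR_DIELECTRIC
from .grids import GridPotential

__all__ = [
    "ParticleSpec",
    "SystemGeometry",
    "EnergyBreakdown",
    "pair_interaction",
    "restraint_energy",
    "grid_value_and_force",
    "total_energy",
]


@dataclass(frozen=True)
class ParticleSpec:
    """Lennard-Jones sphere standing in for one PIP2 molecule.

    charge in e, lj_well_depth (eps) in kcal/mol, lj_rmin_half (rmin/2)
    in A, mass in amu.
    """

    charge: float = -4.0
    lj_well_depth: float = 0.5
    lj_rmin_half: float = 5.4
    mass: float = 1043.0

    def __post_init__(self) -> None:
        if self.lj_well_depth <= 0:
            raise ValueError("lj_well_depth must be positive")
        if self.lj_rmin_half <= 0:
            raise ValueError("lj_rmin_half must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")


@dataclass
class SystemGeometry:
    """Simulation box, corral boundary and restraint constants.

    The diffusion plane sits ``membrane_offset`` (5 A) above the lipid
    phosphate plane; in the simulation frame the plane is at
    ``diffusion_plane_z``.  Hard walls are harmonic one-sided restraints
    at the box edges; the corral is the region x < corral_boundary_x.
    """

    box_x_lo: float = -475.0
    box_x_hi: float = 925.0
    box_y_lo: float = -500.0
    box_y_hi: float = 500.0
    corral_boundary_x: float = 0.0
    diffusion_plane_z: float = 0.0
    membrane_offset: float = 5.0
    planar_force_constant: float = 0.6
    wall_force_constant: float = 100.0

    def __post_init__(self) -> None:
        if not (self.box_x_lo < self.corral_boundary_x < self.box_x_hi):
            raise ValueError("corral boundary must lie inside the box in x")
        if self.box_y_lo >= self.box_y_hi:
            raise ValueError("box_y_lo must be below box_y_hi")
        if self.planar_force_constant <= 0 or self.wall_force_constant <= 0:
            raise ValueError("force constants must be positive")

    @property
    def corral_area(self) -> float:
        """Area of the pool region (x < corral boundary) in A^2."""
        return (self.corral_boundary_x - self.box_x_lo) * (self.box_y_hi - self.box_y_lo)

    @property
    def box_area(self) -> float:
        return (self.box_x_hi - self.box_x_lo) * (self.box_y_hi - self.box_y_lo)

    def scaled(self, factor: float) -> "SystemGeometry":
        """Geometry shrunk by ``factor`` about the corral boundary."""
        return SystemGeometry(
            box_x_lo=self.corral_boundary_x + (self.box_x_lo - self.corral_boundary_x) * factor,
            box_x_hi=self.corral_boundary_x + (self.box_x_hi - self.corral_boundary_x) * factor,
            box_y_lo=self.box_y_lo * factor,
            box_y_hi=self.box_y_hi * factor,
            corral_boundary_x=self.corral_boundary_x,
            diffusion_plane_z=self.diffusion_plane_z,
            membrane_offset=self.membrane_offset,
            planar_force_constant=self.planar_force_constant,
            wall_force_constant=self.wall_force_constant,
        )


@dataclass
class EnergyBreakdown:
    """Per-term decomposition of the total energy (kcal/mol)."""

    pair_lj: float = 0.0
    pair_coulomb: float = 0.0
    core_grid: float = 0.0
    phix_grid: float = 0.0
    planar_restraint: float = 0.0
    wall_restraint: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.pair_lj
            + self.pair_coulomb
            + self.core_grid
            + self.phix_grid
            + self.planar_restraint
            + self.wall_restraint
        )


def combine_lj(p1: ParticleSpec, p2: ParticleSpec) -> tuple[float, float]:
    """Lorentz-Berthelot combination: (rmin, eps) for a pair."""
    rmin = p1.lj_rmin_half + p2.lj_rmin_half
    eps = float(np.sqrt(p1.lj_well_depth * p2.lj_well_depth))
    return rmin, eps


def pair_interaction(
    r: float | np.ndarray,
    p1: ParticleSpec,
    p2: ParticleSpec,
    cutoff: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """LJ + water-screened Coulomb energy and radial force of one pair.

    Returns (energy kcal/mol, radial force kcal/mol/A); the force is
    -dU/dr (positive = repulsive).  With ``cutoff`` set, the potential
    is shifted to zero at the cutoff and vanishes beyond it (test
    profile only; the reference model uses no cutoff).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    rmin, eps = combine_lj(p1, p2)
    sr6 = (rmin / r) ** 6
    lj = eps * (sr6**2 - 2.0 * sr6)
    qq = COULOMB_CONSTANT * p1.charge * p2.charge / PAIR_DIELECTRIC
    coul = qq / r
    u = lj + coul
    f = 12.0 * eps * (sr6**2 - sr6) / r + qq / r**2
    if cutoff is not None:
        rc6 = (rmin / cutoff) ** 6
        u_shift = eps * (rc6**2 - 2.0 * rc6) + qq / cutoff
        u = np.where(r < cutoff, u - u_shift, 0.0)
        f = np.where(r < cutoff, f, 0.0)
    return u, f


def restraint_energy(
    position: np.ndarray, geometry: SystemGeometry
) -> tuple[float, np.ndarray, float, float]:
    """Planar + hard-wall restraint energy and force at one position.

    Returns (energy, force (3,), planar part, wall part).  Convention
    U = k*delta^2 (no 1/2), so a 1 A off-plane displacement costs
    exactly the planar force constant.
    """
    pos = np.asarray(position, dtype=float)
    force = np.zeros(3)
    kp = geometry.planar_force_constant
    dz = pos[2] - geometry.diffusion_plane_z
    planar = kp * dz * dz
    force[2] = -2.0 * kp * dz

    kw = geometry.wall_force_constant
    wall = 0.0
    for axis, lo, hi in (
        (0, geometry.box_x_lo, geometry.box_x_hi),
        (1, geometry.box_y_lo, geometry.box_y_hi),
    ):
        if pos[axis] < lo:
            d = pos[axis] - lo
        elif pos[axis] > hi:
            d = pos[axis] - hi
        else:
            continue
        wall += kw * d * d
        force[axis] += -2.0 * kw * d
    return planar + wall, force, planar, wall


def grid_value_and_force(
    point: np.ndarray, grid: GridPotential, charge: float = 1.0
) -> tuple[float, np.ndarray]:
    """Grid energy contribution and force at a point.

    For an energy map (U^CORE) pass charge=1; for an electrostatic map
    (phi^PHIX, kcal/mol/e) pass the particle charge.  Force is the
    analytic negative gradient of the spline interpolant.
    """
    val, grad = grid.interpolate(np.asarray(point, dtype=float))
    return charge * float(val), -charge * np.asarray(grad)


def total_energy(
    positions: np.ndarray,
    spec: ParticleSpec,
    geometry: SystemGeometry,
    core_grid: GridPotential | None = None,
    phix_grid: GridPotential | None = None,
    cutoff: float | None = None,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Total energy breakdown and per-particle forces of a configuration.

    positions : (n, 3) A.  All particles share ``spec`` (the model has a
    single PIP2 species).  Grids are optional; absent maps contribute 0.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    eb = EnergyBreakdown()

    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(n, k=1)
        r = dist[iu]
        if np.any(r == 0):
            raise ValueError("overlapping particles at zero separation")
        rmin, eps = combine_lj(spec, spec)
        sr6 = (rmin / r) ** 6
        lj = eps * (sr6**2 - 2.0 * sr6)
        qq = COULOMB_CONSTANT * spec.charge**2 / PAIR_DIELECTRIC
        coul = qq / r
        fmag = 12.0 * eps * (sr6**2 - sr6) / r + qq / r**2
        if cutoff is not None:
            rc6 = (rmin / cutoff) ** 6
            mask = r < cutoff
            lj = np.where(mask, lj - eps * (rc6**2 - 2.0 * rc6), 0.0)
            coul = np.where(mask, coul - qq / cutoff, 0.0)
            fmag = np.where(mask, fmag, 0.0)
        eb.pair_lj = float(lj.sum())
        eb.pair_coulomb = float(coul.sum())
        # scatter pair forces
        unit = diff[iu] / r[:, None]
        fvec = fmag[:, None] * unit
        np.add.at(forces, iu[0], fvec)
        np.add.at(forces, iu[1], -fvec)

    for i in range(n):
        e, f, planar, wall = restraint_energy(pos[i], geometry)
        eb.planar_restraint += planar
        eb.wall_restraint += wall
        forces[i] += f
        if core_grid is not None:
            e, f = grid_value_and_force(pos[i], core_grid, 1.0)
            eb.core_grid += e
            forces[i] += f
        if phix_grid is not None:
            e, f = grid_value_and_force(pos[i], phix_grid, spec.charge)
            eb.phix_grid += e
            forces[i] += f
    return eb, forces
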