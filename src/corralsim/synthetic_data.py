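"""Synthetic inputs: system recipes, pseudo-filaments, and analytic oracles.

Everything the pipeline consumes can be generated here, at full
reference scale or a shrunk "desk" scale for fast runs: initial sphere
placements in the corral at 6% concentration, bead-chain pseudo-protein
filaments (flat wall or arch profiles mimicking septin- and actin-like
cross-sections), a closed-form 1D diffusion oracle for free depletion,
and noisy stretched-exponential decay curves for fit validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .analysis import DEFAULT_AREA_PER_LIPID, DepletionSeries, stretched_exponential
from .fences import FenceAtoms
from .model_core import ParticleSpec, SystemGeometry

__all__ = [
    "SystemRecipe",
    "PseudoFilamentSpec",
    "SCENARIO_GEOMETRY",
    "make_system",
    "make_pseudo_filament",
    "continuum_free_diffusion",
    "make_decay_curve",
    "desk_profile",
]

#: Reference box layouts per fence scenario (x_lo, x_hi, y half-width).
SCENARIO_GEOMETRY: dict[str, tuple[float, float, float]] = {
    "steric_rod": (-475.0, 925.0, 500.0),
    "electrostatic_rod": (-475.0, 925.0, 225.0),
    "protein": (-475.0, 925.0, 375.0),
}


@dataclass(frozen=True)
class SystemRecipe:
    """Scenario + scale -> geometry and initial particle placement.

    scale_factor shrinks the box about the corral boundary; the
    particle count follows from the 6% target concentration and the 65
    A^2 area per lipid, so box and count shrink together.
    """

    scenario: str = "steric_rod"
    target_corral_concentration: float = 6.0  # mol% of lipids
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID
    scale_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_GEOMETRY:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.scale_factor <= 1):
            raise ValueError("scale factor must lie in (0, 1]")
        if self.target_corral_concentration <= 0 or self.area_per_lipid <= 0:
            raise ValueError("concentration and area per lipid must be positive")

    def geometry(self) -> SystemGeometry:
        x_lo, x_hi, y_half = SCENARIO_GEOMETRY[self.scenario]
        geo = SystemGeometry(
            box_x_lo=x_lo, box_x_hi=x_hi, box_y_lo=-y_half, box_y_hi=y_half
        )
        return geo.scaled(self.scale_factor) if self.scale_factor != 1.0 else geo

    def particle_count(self) -> int:
        geo = self.geometry()
        return int(
            round(
                self.target_corral_concentration
                / 100.0
                * geo.corral_area
                / self.area_per_lipid
            )
        )

    def uniform_concentration(self) -> float:
        """Concentration if the corral's spheres spread over the whole box."""
        geo = self.geometry()
        return (
            100.0 * self.particle_count() * self.area_per_lipid / geo.box_area
        )


def make_system(
    recipe: SystemRecipe,
    particle: ParticleSpec | None = None,
    exclusion_points: np.ndarray | None = None,
    max_attempts: int = 200,
) -> tuple[SystemGeometry, int, np.ndarray]:
    """Geometry plus initial positions sampled uniformly in the corral.

    Placement uses minimum-separation rejection (pairwise >= the LJ
    contact distance, and likewise against ``exclusion_points`` such as
    fence spheres) with all spheres on the diffusion plane.
    """
    if particle is None:
        particle = ParticleSpec()
    geo = recipe.geometry()
    n = recipe.particle_count()
    rmin = 2.0 * particle.lj_rmin_half
    rng = np.random.default_rng(recipe.seed)
    margin = particle.lj_rmin_half
    x_lo, x_hi = geo.box_x_lo + margin, geo.corral_boundary_x - margin
    y_lo, y_hi = geo.box_y_lo + margin, geo.box_y_hi - margin
    if (x_hi - x_lo) * (y_hi - y_lo) < n * rmin**2:
        raise ValueError("requested density cannot be deposited in the corral")

    placed = np.empty((0, 3))
    for _ in range(max_attempts):
        need = n - len(placed)
        cand = np.column_stack(
            [
                rng.uniform(x_lo, x_hi, size=4 * need),
                rng.uniform(y_lo, y_hi, size=4 * need),
                np.full(4 * need, geo.diffusion_plane_z),
            ]
        )
        for p in cand:
            if len(placed) and np.min(np.linalg.norm(placed - p, axis=1)) < rmin:
                continue
            if exclusion_points is not None and len(exclusion_points):
                if np.min(np.linalg.norm(exclusion_points - p, axis=1)) < rmin:
                    continue
            placed = np.vstack([placed, p])
            if len(placed) == n:
                return geo, n, placed
    raise RuntimeError(
        f"could not place {n} spheres after {max_attempts} rounds of rejection sampling"
    )


# ---------------------------------------------------------------------------
# pseudo-protein filaments


@dataclass(frozen=True)
class PseudoFilamentSpec:
    """Bead-chain stand-in for a filament monomer (synthetic).

    The monomer is a one-bead-thick wall in the Y-Z plane at X = 0:
    columns of beads every ``bead_spacing`` along Y, stacked from the
    bottom profile up to ``wall_height``.  ``profile`` selects the
    bottom edge: "flat" (septin-like continuous footprint) or "arch"
    (actin-like, the bottom rises by ``arch_gap_height`` mid-subunit,
    leaving an under-filament channel even when the feet are buried).
    Residue labels cycle through a fixed charged/hydrophobic/neutral
    pattern so charge assignment and burial counting work end to end.
    """

    subunit_length: float = 81.0
    wall_height: float = 40.0
    profile: str = "flat"
    arch_gap_height: float = 30.0
    bead_spacing: float = 4.0
    bead_radius: float = 2.0
    residue_cycle: tuple[str, ...] = ("LYS", "LEU", "SER", "ASP", "PHE", "ARG", "ALA", "GLU")

    def __post_init__(self) -> None:
        if self.profile not in ("flat", "arch"):
            raise ValueError("profile must be 'flat' or 'arch'")
        if self.bead_spacing <= 0 or self.bead_radius <= 0:
            raise ValueError("bead spacing and radius must be positive")
        if not (0 < self.arch_gap_height < self.wall_height + self.arch_gap_height):
            raise ValueError("arch gap height must be positive")


def make_pseudo_filament(
    spec: PseudoFilamentSpec, path: str | Path | None = None
) -> FenceAtoms:
    """Build (and optionally write as PDB) one pseudo-filament subunit.

    Coordinates are in the phosphate-plane frame with the lowest bead
    at Z = 0 (i.e. as placed at Z_min = 0).  Charges follow the formal
    charge table through the residue labels.
    """
    from .fences import RESIDUE_FORMAL_CHARGE, write_structure

    coords = []
    residues: list[str] = []
    n_cols = max(2, int(round(spec.subunit_length / spec.bead_spacing)))
    idx = 0
    for c in range(n_cols):
        y = c * spec.bead_spacing
        if spec.profile == "arch":
            z_bot = spec.arch_gap_height * math.sin(math.pi * c / (n_cols - 1))
        else:
            z_bot = 0.0
        z = z_bot
        while z <= z_bot + spec.wall_height + 1e-9:
            coords.append((0.0, y, z))
            residues.append(spec.residue_cycle[idx % len(spec.residue_cycle)])
            idx += 1
            z += spec.bead_spacing
    charges = np.array([RESIDUE_FORMAL_CHARGE.get(r, 0.0) for r in residues])
    atoms = FenceAtoms(
        coords=np.array(coords),
        charges=charges,
        radii=np.full(len(coords), spec.bead_radius),
        residues=residues,
        steric=True,
    )
    if path is not None:
        write_structure(atoms, path)
    return atoms


# ---------------------------------------------------------------------------
# analytic oracles


def continuum_free_diffusion(
    geometry: SystemGeometry,
    diffusion_constant: float,
    times: np.ndarray,
    initial_concentration: float = 6.0,
    rtol: float = 1e-10,
    max_terms: int = 100_000,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Windowed concentration (%) of 1D continuum diffusion, reflecting walls.

    The initial condition is a step profile filling the corral
    (x < corral boundary) at ``initial_concentration``; the solution is
    the Fourier-cosine series on [x_lo, x_hi].  By default the returned
    series is the concentration averaged over the pool window
    (x_lo, corral boundary); any other averaging window inside the box
    may be requested.  Terms are added until the truncated tail is
    below ``rtol`` at the earliest positive time; each cosine mode
    integrates to zero over the box, so mass is conserved term by term.
    """
    times = np.asarray(times, dtype=float)
    if diffusion_constant <= 0:
        raise ValueError("diffusion constant must be positive")
    L = geometry.box_x_hi - geometry.box_x_lo
    a = geometry.corral_boundary_x - geometry.box_x_lo  # corral width
    c0 = initial_concentration
    if window is None:
        w0, w1 = 0.0, a
    else:
        w0, w1 = window[0] - geometry.box_x_lo, window[1] - geometry.box_x_lo
    if not (0 <= w0 < w1 <= L):
        raise ValueError("window must lie inside the box")

    t_ref = times[times > 0].min() if np.any(times > 0) else None
    conc = np.full(times.shape, c0 * a / L)
    n = 1
    while n <= max_terms:
        k = n * math.pi / L
        mode_amp = 2.0 * c0 * math.sin(k * a) / (k * L)  # projection of the step
        window_avg = mode_amp * (math.sin(k * w1) - math.sin(k * w0)) / (k * (w1 - w0))
        conc = conc + window_avg * np.exp(-diffusion_constant * k * k * times)
        if t_ref is not None:
            tail = abs(mode_amp) * math.exp(-diffusion_constant * k * k * t_ref)
            if tail < rtol * c0 and n > 10:
                break
        elif n > 1000:
            break
        n += 1
    # at t = 0 the series converges only pointwise (Gibbs); the initial
    # condition is exact: the window average of the step profile
    if np.any(times == 0):
        overlap = max(0.0, min(w1, a) - min(w0, a))
        conc = np.where(times == 0, c0 * overlap / (w1 - w0), conc)
    return conc


def make_decay_curve(
    c0: float,
    c_inf: float,
    tau: float,
    beta: float,
    noise_sd: float,
    n_points: int,
    t_max: float,
    seed: int = 0,
    n_replicas: int = 1,
) -> DepletionSeries:
    """Stretched-exponential decay samples with Gaussian noise.

    Deterministic given the seed; replicas share the noiseless backbone
    and differ only in noise.
    """
    if tau <= 0 or not (0 < beta <= 2):
        raise ValueError("tau must be positive and beta in (0, 2]")
    times = np.linspace(0.0, t_max, n_points)
    backbone = stretched_exponential(times, c_inf, tau, beta, c0)
    rng = np.random.default_rng(seed)
    noisy = backbone[None, :] + noise_sd * rng.standard_normal((n_replicas, n_points))
    return DepletionSeries(times=times, per_replica=noisy)


@dataclass(frozen=True)
class DeskProfile:
    """Shrunk test conditions: only relaxation-time *ratios* are read."""

    scale_factor: float = 0.25
    friction: float = 0.1  # 1/ps (raises D, shortening relaxation times)
    timestep: float = 0.02  # ps; stable for the slow 1043 amu spheres
    n_replicas: int = 12
    equilibration_time: float = 500.0  # ps
    production_time: float = 10_000.0  # ps
    snapshot_interval: float = 20.0  # ps
    pair_cutoff: float = 40.0  # A, energy-shifted truncation


def desk_profile() -> DeskProfile:
    return DeskProfile()
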