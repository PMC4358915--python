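"""Effective grid potentials: the steric core map and the implicit-membrane
linearized Poisson-Boltzmann electrostatic map.

The fence acts on the simulated spheres only through two precomputed
fields: ``U^CORE`` (0 inside accessible space, 100 kcal/mol inside the
fence atoms' augmented radii) and ``phi^PHIX``, the electrostatic
potential of the fence charges in a three-dielectric environment -- a
36 A membrane slab (eps 2) below the phosphate plane, solvent (eps 80,
150 mM 1:1 salt) above, and eps-2 cavities for the fence atoms.

The PB equation is solved in its linearized (Debye-Huckel) form on a
regular 7-point finite-difference stencil:

    div(eps grad phi) - eps_s kappa^2 lambda(r) phi = -4 pi k_e rho,

with lambda = 1 in the salt-accessible solvent, 0 in membrane and
solute.  Dirichlet boundary values come from a sum of screened
single-charge potentials (standard focusing practice), and the solution
is focused through a schedule of successively finer grids, each taking
its boundary values from the previous level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg
from scipy.spatial import cKDTree

from .constants import COULOMB_CONSTANT, debye_kappa
from .fences import FenceAtoms, RodFenceSpec, build_electrostatic_rod
from .grids import GridPotential

__all__ = [
    "PBEnvironment",
    "FocusingSchedule",
    "GridBox",
    "build_core_map",
    "solve_pb",
    "rod_interaction_profile",
    "pip_rod_binding_energy",
    "potential_map_slice",
]


@dataclass(frozen=True)
class PBEnvironment:
    """Dielectric / salt environment of the implicit membrane system.

    The membrane slab occupies membrane_top_z - thickness < z <
    membrane_top_z (phosphate plane at z = 0 by default).  Salt is
    present only in the solvent region.
    """

    membrane_thickness: float = 36.0
    membrane_dielectric: float = 2.0
    solvent_dielectric: float = 80.0
    solute_dielectric: float = 2.0
    salt_mM: float = 150.0
    temperature: float = 300.0
    membrane_top_z: float = 0.0

    def __post_init__(self) -> None:
        if min(self.membrane_dielectric, self.solvent_dielectric, self.solute_dielectric) <= 0:
            raise ValueError("dielectrics must be positive")
        if self.membrane_thickness < 0:
            raise ValueError("membrane thickness must be non-negative")

    @property
    def kappa(self) -> float:
        """Inverse Debye length (1/A) of the solvent region."""
        return debye_kappa(self.salt_mM / 1000.0, self.solvent_dielectric, self.temperature)


@dataclass(frozen=True)
class GridBox:
    """Axis-aligned solve region with a node spacing."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError("box upper corner must exceed lower corner")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for lo, hi in zip(self.lo, self.hi):
            n = int(round((hi - lo) / self.spacing)) + 1
            out.append(lo + self.spacing * np.arange(n))
        return tuple(out)


@dataclass(frozen=True)
class FocusingSchedule:
    """Coarse-to-fine grid focusing parameters."""

    coarse_spacing: float = 1.0
    fine_spacing: float = 0.5
    coarse_margin: float = 40.0  # A added to the fine box on every side

    def __post_init__(self) -> None:
        if self.fine_spacing > self.coarse_spacing:
            raise ValueError("fine spacing must not exceed coarse spacing")

    def levels(self, fine_box: GridBox) -> list[GridBox]:
        m = self.coarse_margin
        coarse = GridBox(
            lo=tuple(v - m for v in fine_box.lo),
            hi=tuple(v + m for v in fine_box.hi),
            spacing=self.coarse_spacing,
        )
        return [coarse, GridBox(fine_box.lo, fine_box.hi, self.fine_spacing)]


# ---------------------------------------------------------------------------
# core repulsion map


def build_core_map(
    atoms: FenceAtoms,
    box: GridBox,
    augmentation: float = 4.16,
    height: float = 100.0,
) -> GridPotential:
    """Binary exclusion map: ``height`` inside any augmented-radius sphere.

    The augmentation (4.16 A) grows each atom's radius by the effective
    probe size of a PIP2 sphere, so the map marks space the *center* of
    a simulated sphere cannot reach.
    """
    xs, ys, zs = box.axes()
    values = np.zeros((len(xs), len(ys), len(zs)))
    if atoms.n_atoms:
        if np.any(atoms.radii <= 0):
            raise ValueError("atom radii must be positive")
        h = box.spacing
        for center, radius in zip(atoms.coords, atoms.radii):
            r = radius + augmentation
            i0 = np.searchsorted(xs, center[0] - r)
            i1 = np.searchsorted(xs, center[0] + r, side="right")
            j0 = np.searchsorted(ys, center[1] - r)
            j1 = np.searchsorted(ys, center[1] + r, side="right")
            k0 = np.searchsorted(zs, center[2] - r)
            k1 = np.searchsorted(zs, center[2] + r, side="right")
            if i0 >= i1 or j0 >= j1 or k0 >= k1:
                continue
            dx2 = (xs[i0:i1] - center[0]) ** 2
            dy2 = (ys[j0:j1] - center[1]) ** 2
            dz2 = (zs[k0:k1] - center[2]) ** 2
            inside = (
                dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
            ) <= r * r
            sub = values[i0:i1, j0:j1, k0:k1]
            sub[inside] = height
    return GridPotential(
        origin=np.array([xs[0], ys[0], zs[0]]),
        spacing=np.full(3, box.spacing),
        values=values,
        boundary="clamp",
        name="U_CORE",
    )


# ---------------------------------------------------------------------------
# linearized PB solver


class _RegionTester:
    """Classifies points into solute / membrane / solvent."""

    def __init__(self, coords: np.ndarray, radii: np.ndarray, env: PBEnvironment):
        self.env = env
        self._groups: list[tuple[cKDTree, float]] = []
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        radii = np.asarray(radii, dtype=float).reshape(-1)
        if len(coords):
            for r in np.unique(radii):
                if r <= 0:
                    continue
                sel = radii == r
                self._groups.append((cKDTree(coords[sel]), float(r)))

    def in_solute(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        inside = np.zeros(len(pts), dtype=bool)
        for tree, r in self._groups:
            todo = ~inside
            if not todo.any():
                break
            d, _ = tree.query(pts[todo], k=1)
            inside[todo] = d <= r
        return inside

    def in_membrane(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        env = self.env
        if env.membrane_thickness == 0:
            return np.zeros(len(pts), dtype=bool)
        z = pts[:, 2]
        return (z <= env.membrane_top_z) & (z >= env.membrane_top_z - env.membrane_thickness)

    def epsilon(self, points: np.ndarray) -> np.ndarray:
        env = self.env
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        eps = np.full(len(pts), env.solvent_dielectric)
        mem = self.in_membrane(pts)
        eps[mem] = env.membrane_dielectric
        sol = self.in_solute(pts)
        eps[sol] = env.solute_dielectric
        return eps

    def salt_accessible(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return ~(self.in_membrane(pts) | self.in_solute(pts))


def _screened_potential(
    points: np.ndarray, coords: np.ndarray, charges: np.ndarray, env: PBEnvironment
) -> np.ndarray:
    """Sum of Debye-Huckel single-charge potentials (kcal/mol/e)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    kappa = env.kappa
    eps = env.solvent_dielectric
    phi = np.zeros(len(pts))
    chunk = 200
    for s in range(0, len(coords), chunk):
        d = np.linalg.norm(pts[:, None, :] - coords[s : s + chunk][None, :, :], axis=-1)
        d = np.maximum(d, 1e-6)
        phi += (
            COULOMB_CONSTANT
            * (charges[s : s + chunk][None, :] * np.exp(-kappa * d) / (eps * d))
        ).sum(axis=1)
    return phi


def _spread_charges(
    coords: np.ndarray, charges: np.ndarray, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray
) -> np.ndarray:
    """Trilinear (cloud-in-cell) assignment of point charges to nodes."""
    grid = np.zeros((len(xs), len(ys), len(zs)))
    h = (xs[1] - xs[0], ys[1] - ys[0], zs[1] - zs[0])
    origin = (xs[0], ys[0], zs[0])
    for (x, y, z), q in zip(coords, charges):
        u = [(x - origin[0]) / h[0], (y - origin[1]) / h[1], (z - origin[2]) / h[2]]
        i0 = [int(np.floor(v)) for v in u]
        f = [u[a] - i0[a] for a in range(3)]
        for da in (0, 1):
            wa = (1 - f[0]) if da == 0 else f[0]
            ia = i0[0] + da
            if not (0 <= ia < len(xs)):
                continue
            for db in (0, 1):
                wb = (1 - f[1]) if db == 0 else f[1]
                ib = i0[1] + db
                if not (0 <= ib < len(ys)):
                    continue
                for dc in (0, 1):
                    wc = (1 - f[2]) if dc == 0 else f[2]
                    ic = i0[2] + dc
                    if not (0 <= ic < len(zs)):
                        continue
                    grid[ia, ib, ic] += q * wa * wb * wc
    return grid


def _solve_level(
    box: GridBox,
    tester: _RegionTester,
    coords: np.ndarray,
    charges: np.ndarray,
    env: PBEnvironment,
    boundary_values: np.ndarray,
    x0_full: np.ndarray | None,
    rtol: float,
    maxiter: int,
) -> GridPotential:
    xs, ys, zs = box.axes()
    nx, ny, nz = len(xs), len(ys), len(zs)
    if min(nx, ny, nz) < 3:
        raise ValueError("grid too small for the 7-point stencil")
    h = box.spacing

    # face dielectric constants at face midpoints
    def face_eps(axis: int) -> np.ndarray:
        ax = [xs, ys, zs]
        mids = ax[axis][:-1] + h / 2.0
        shape = [nx, ny, nz]
        shape[axis] -= 1
        pts = np.stack(
            np.meshgrid(
                mids if axis == 0 else xs,
                mids if axis == 1 else ys,
                mids if axis == 2 else zs,
                indexing="ij",
            ),
            axis=-1,
        ).reshape(-1, 3)
        return tester.epsilon(pts).reshape(shape)

    eps_x = face_eps(0)
    eps_y = face_eps(1)
    eps_z = face_eps(2)

    nodes = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    kappa = env.kappa
    if kappa > 0:
        lam = tester.salt_accessible(nodes).reshape(nx, ny, nz)
        kbar2 = env.solvent_dielectric * kappa**2 * lam
    else:
        kbar2 = np.zeros((nx, ny, nz))

    q_grid = _spread_charges(coords, charges, xs, ys, zs)

    interior = np.zeros((nx, ny, nz), dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    idx = -np.ones((nx, ny, nz), dtype=np.int64)
    n_in = int(interior.sum())
    idx[interior] = np.arange(n_in)

    diag = (kbar2 * h * h)[interior].copy()
    b = (4.0 * math.pi * COULOMB_CONSTANT * q_grid / h)[interior].copy()

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag_full = np.zeros((nx, ny, nz))
    b_full = np.zeros((nx, ny, nz))

    for axis, eps_f in ((0, eps_x), (1, eps_y), (2, eps_z)):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        ids_a = idx[tuple(sl_a)]
        ids_b = idx[tuple(sl_b)]
        # every face adds eps to the diagonal of its interior endpoints
        diag_full[tuple(sl_a)] += eps_f
        diag_full[tuple(sl_b)] += eps_f
        both = (ids_a >= 0) & (ids_b >= 0)
        rows.append(ids_a[both])
        cols.append(ids_b[both])
        vals.append(-eps_f[both])
        rows.append(ids_b[both])
        cols.append(ids_a[both])
        vals.append(-eps_f[both])
        # faces crossing the boundary contribute eps*phi_b to the rhs
        a_only = (ids_a >= 0) & (ids_b < 0)
        if a_only.any():
            bc = boundary_values[tuple(sl_b)]
            upd = np.zeros_like(eps_f)
            upd[a_only] = eps_f[a_only] * bc[a_only]
            b_full[tuple(sl_a)] += upd
        b_only = (ids_b >= 0) & (ids_a < 0)
        if b_only.any():
            bc = boundary_values[tuple(sl_a)]
            upd = np.zeros_like(eps_f)
            upd[b_only] = eps_f[b_only] * bc[b_only]
            b_full[tuple(sl_b)] += upd

    diag = diag + diag_full[interior]
    b = b + b_full[interior]

    A = sparse.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (
                np.concatenate(rows + [np.arange(n_in)]),
                np.concatenate(cols + [np.arange(n_in)]),
            ),
        ),
        shape=(n_in, n_in),
    ).tocsr()

    M = sparse.diags(1.0 / diag)
    x0 = x0_full[interior] if x0_full is not None else None
    phi_in, info = cg(A, b, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ phi_in - b) / max(np.linalg.norm(b), 1e-300)
        raise RuntimeError(f"PB solver did not converge (info={info}, residual={res:.2e})")

    phi = boundary_values.copy()
    phi[interior] = phi_in
    return GridPotential(
        origin=np.array([xs[0], ys[0], zs[0]]),
        spacing=np.full(3, h),
        values=phi,
        boundary="clamp",
        name="phi_PHIX",
    )


def solve_pb(
    atoms: FenceAtoms,
    env: PBEnvironment,
    fine_box: GridBox,
    schedule: FocusingSchedule | list[GridBox] | None = None,
    bc_coords: np.ndarray | None = None,
    bc_charges: np.ndarray | None = None,
    rtol: float = 1e-8,
    maxiter: int = 20000,
    return_levels: bool = False,
):
    """Solve the linearized PB equation by coarse-to-fine focusing.

    ``atoms`` supplies sources (charges at atom centers) and eps-2
    cavities (atoms with positive radii).  ``bc_coords/bc_charges``
    optionally extend the charge set used for the *outer* Dirichlet
    boundary only -- e.g. the full length of a rod when the solve region
    covers a short Y-section of it.  Returns the finest grid (kcal/mol/e),
    or the whole level list when ``return_levels`` is set.
    """
    if schedule is None:
        schedule = FocusingSchedule()
    levels = schedule.levels(fine_box) if isinstance(schedule, FocusingSchedule) else list(schedule)

    coords = np.asarray(atoms.coords, dtype=float).reshape(-1, 3)
    charges = np.asarray(atoms.charges, dtype=float).reshape(-1)
    tester = _RegionTester(coords, atoms.radii, env)
    if bc_coords is None:
        bc_coords, bc_charges = coords, charges
    else:
        bc_coords = np.asarray(bc_coords, dtype=float).reshape(-1, 3)
        bc_charges = np.asarray(bc_charges, dtype=float).reshape(-1)

    solved: list[GridPotential] = []
    prev: GridPotential | None = None
    for level, box in enumerate(levels):
        xs, ys, zs = box.axes()
        shape = (len(xs), len(ys), len(zs))
        boundary = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        mask[0, :, :] = mask[-1, :, :] = True
        mask[:, 0, :] = mask[:, -1, :] = True
        mask[:, :, 0] = mask[:, :, -1] = True
        pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        bpts = pts[mask]
        x0_full = None
        if prev is None:
            boundary[mask] = _screened_potential(bpts, bc_coords, bc_charges, env)
        else:
            boundary[mask] = _interp_grid(prev, bpts)
            x0_full = _interp_grid(prev, pts.reshape(-1, 3)).reshape(shape)
        grid = _solve_level(
            box, tester, coords, charges, env, boundary, x0_full, rtol, maxiter
        )
        solved.append(grid)
        prev = grid
    return solved if return_levels else solved[-1]


def _interp_grid(grid: GridPotential, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a grid at arbitrary points (clamped)."""
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        tuple(grid.axis_coords(a) for a in range(3)),
        grid.values,
        bounds_error=False,
        fill_value=None,
    )
    return interp(np.asarray(points, dtype=float).reshape(-1, 3))


# ---------------------------------------------------------------------------
# rod profiles and combined maps


def rod_interaction_profile(
    spec: RodFenceSpec,
    env: PBEnvironment | None = None,
    test_charge: float = -4.0,
    plane_z: float = 5.0,
    x_half_extent: float = 30.0,
    y_half_extent: float = 27.0,
    schedule: FocusingSchedule | None = None,
    rtol: float = 1e-7,
) -> dict:
    """PB interaction energy of a test sphere with a charged rod vs X.

    The rod runs along Y at X = 0, raised ``spec.height`` above the
    diffusion plane (itself ``plane_z`` above the phosphate plane, the
    frame used here).  The solve region is a short Y-section of the rod
    at fine spacing; the Dirichlet boundary uses the full rod length.
    Returns the profile U(X) = q_test * phi(X, 0, plane_z) referenced to
    its far-field value, its barrier (max) and well depth (-min).
    """
    if env is None:
        env = PBEnvironment()
    if schedule is None:
        schedule = FocusingSchedule()
    full_rod = build_electrostatic_rod(spec, plane_z=plane_z)

    # restrict explicit atoms to the solve section; keep the full rod for BCs
    sect = np.abs(full_rod.coords[:, 1]) <= y_half_extent + schedule.coarse_margin
    atoms = FenceAtoms(
        coords=full_rod.coords[sect],
        charges=full_rod.charges[sect],
        radii=full_rod.radii[sect],
        steric=False,
    )
    z_lo = plane_z - 11.0
    z_hi = plane_z + spec.height + 12.0
    fine_box = GridBox(
        lo=(-x_half_extent, -y_half_extent, z_lo),
        hi=(x_half_extent, y_half_extent, z_hi),
        spacing=schedule.fine_spacing,
    )
    levels = solve_pb(
        atoms,
        env,
        fine_box,
        schedule=schedule,
        bc_coords=full_rod.coords,
        bc_charges=full_rod.charges,
        rtol=rtol,
        return_levels=True,
    )
    coarse, fine = levels[0], levels[-1]

    xs = fine.axis_coords(0)
    pts = np.column_stack([xs, np.zeros_like(xs), np.full_like(xs, plane_z)])
    vals, _ = fine.interpolate(pts)
    u = test_charge * vals

    # far-field reference from the coarse grid edge on the same line
    cx = coarse.axis_coords(0)
    margin = 3 * coarse.spacing[0]
    far_x = np.array([cx[0] + margin, cx[-1] - margin])
    far_pts = np.column_stack([far_x, np.zeros(2), np.full(2, plane_z)])
    far_vals, _ = coarse.interpolate(far_pts)
    u_far = test_charge * float(far_vals.mean())

    profile = u - u_far
    return {
        "x": xs,
        "energy": profile,
        "barrier": float(profile.max()),
        "well_depth": float(-profile.min()),
        "far_field": u_far,
        "fine_grid": fine,
        "coarse_grid": coarse,
    }


def _charge_grid_energy(
    atoms: FenceAtoms, levels: list[GridPotential]
) -> float:
    """G = 1/2 sum q_i phi(r_i), each charge read off the finest grid
    that contains it with margin.  Grid self-energies are identical
    across solves that share grids and charge positions, so they cancel
    in binding-energy differences."""
    fine = levels[-1]
    coarse = levels[0]
    total = 0.0
    for c, q in zip(atoms.coords, atoms.charges):
        if q == 0.0:
            continue
        inside_fine = np.all(c >= fine.origin + 1.0) and np.all(
            c <= fine.upper_corner - 1.0
        )
        grid = fine if inside_fine else coarse
        v, _ = grid.interpolate(c)
        total += 0.5 * q * float(v)
    return total


def pip_rod_binding_energy(
    spec: RodFenceSpec,
    env: PBEnvironment | None = None,
    x_position: float = 0.0,
    test_charge: float = -4.0,
    test_radius: float = 5.4,
    plane_z: float = 5.0,
    x_half_extent: float = 30.0,
    y_half_extent: float = 27.0,
    y_section: float = 60.0,
    schedule: FocusingSchedule | None = None,
    rtol: float = 1e-8,
    component: str = "electrostatic",
) -> float:
    """PB interaction energy of one PIP2 sphere with a charged rod (kcal/mol).

    The PIP2 is a -4e charge inside its own eps-2 sphere at
    (x_position, 0, plane_z).  Two components are available, both from
    focused solves on identical grids so grid self-energies cancel:

    * ``component="electrostatic"`` (default): the rod-charging part of
      the interaction,

          dG_elec = G(complex) - G(complex, rod uncharged) - G(rod),

      i.e. the energy the *rod charges* exert on the PIP2 in the full
      dielectric geometry of the complex.  Because the two eps-2
      cavities and the membrane confine the field lines, this is
      several-fold larger than the bare map value q*phi near contact;
      it is the quantity that separates blocking from non-blocking
      rods.

    * ``component="total"``: the full binding energy
      dG = G(complex) - G(rod) - G(PIP2), which additionally contains
      the charge-independent desolvation of the PIP2 by the rod cavity.

    The reference state (infinite separation) is exactly zero by
    construction for both components.
    """
    if component not in ("electrostatic", "total"):
        raise ValueError("component must be 'electrostatic' or 'total'")
    if env is None:
        env = PBEnvironment()
    if schedule is None:
        schedule = FocusingSchedule()
    full_rod = build_electrostatic_rod(spec, plane_z=plane_z)
    sect = np.abs(full_rod.coords[:, 1]) <= y_section
    rod = FenceAtoms(
        coords=full_rod.coords[sect],
        charges=full_rod.charges[sect],
        radii=full_rod.radii[sect],
        steric=False,
    )
    z_hi = plane_z + spec.height + 12.0
    fine_box = GridBox(
        lo=(-x_half_extent, -y_half_extent, plane_z - 11.0),
        hi=(x_half_extent, y_half_extent, z_hi),
        spacing=schedule.fine_spacing,
    )
    pip_c = np.array([[x_position, 0.0, plane_z]])
    pip_q = np.array([test_charge])
    pip_r = np.array([test_radius])

    def solve_G(atoms: FenceAtoms, bc_c: np.ndarray, bc_q: np.ndarray) -> float:
        if np.all(atoms.charges == 0.0):
            return 0.0
        levels = solve_pb(
            atoms, env, fine_box, schedule=schedule,
            bc_coords=bc_c, bc_charges=bc_q, rtol=rtol, return_levels=True,
        )
        return _charge_grid_energy(atoms, levels)

    complex_atoms = FenceAtoms(
        coords=np.vstack([rod.coords, pip_c]),
        charges=np.concatenate([rod.charges, pip_q]),
        radii=np.concatenate([rod.radii, pip_r]),
        steric=False,
    )
    g_complex = solve_G(
        complex_atoms,
        np.vstack([full_rod.coords, pip_c]),
        np.concatenate([full_rod.charges, pip_q]),
    )
    g_rod = solve_G(rod, full_rod.coords, full_rod.charges)
    if component == "electrostatic":
        neutral_complex = FenceAtoms(
            coords=complex_atoms.coords,
            charges=np.concatenate([np.zeros(rod.n_atoms), pip_q]),
            radii=complex_atoms.radii,
            steric=False,
        )
        g_neutral = solve_G(neutral_complex, pip_c, pip_q)
        return g_complex - g_neutral - g_rod
    pip_atoms = FenceAtoms(coords=pip_c, charges=pip_q, radii=pip_r, steric=False)
    g_pip = solve_G(pip_atoms, pip_c, pip_q)
    return g_complex - g_rod - g_pip


def potential_map_slice(
    core_grid: GridPotential | None,
    phix_grid: GridPotential | None,
    test_charge: float = -4.0,
    z: float = 5.0,
    threshold: float = 50.0,
) -> dict:
    """Combined potential U^CORE + q*phi on a plane, with gap detection.

    Flood-fills the sub-threshold region from the low-X edge and reports
    whether any connected channel of passable cells crosses to the
    high-X edge.
    """
    from scipy import ndimage

    ref = core_grid if core_grid is not None else phix_grid
    if ref is None:
        raise ValueError("need at least one grid")
    xs = ref.axis_coords(0)
    ys = ref.axis_coords(1)
    combined = np.zeros((len(xs), len(ys)))
    pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    pts3 = np.column_stack([pts, np.full(len(pts), z)])
    if core_grid is not None:
        v, _ = core_grid.interpolate(pts3)
        combined += v.reshape(len(xs), len(ys))
    if phix_grid is not None:
        v, _ = phix_grid.interpolate(pts3)
        combined += test_charge * v.reshape(len(xs), len(ys))

    passable = combined < threshold
    labels, _ = ndimage.label(passable)
    left = set(labels[0, :][passable[0, :]])
    right = set(labels[-1, :][passable[-1, :]])
    channel = bool(left & right - {0})
    return {"x": xs, "y": ys, "potential": combined, "channel_exists": channel}
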