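"""Regular 3D scalar-field grids with B-spline interpolation and DX I/O.

Fence potentials (the steric core map U^CORE and the Poisson-Boltzmann
electrostatic map phi^PHIX) live on regular lattices.  During dynamics
their values and forces are evaluated with 3rd-order (quadratic)
B-spline interpolation, which is C1-continuous so the interpolated
force is the exact negative gradient of the interpolated energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridPotential", "read_dx", "write_dx", "bspline3_value_gradient"]


@dataclass
class GridPotential:
    """A scalar field on a regular axis-aligned lattice.

    origin : (3,) position of node (0,0,0) in A
    spacing : (3,) node spacing per axis in A
    values : (nx, ny, nz) array; kcal/mol for energy maps, kcal/mol/e
        for electrostatic potential maps.
    boundary : "clamp" or "error" -- what interpolation does outside the
        spline-interpolable interior.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    boundary: str = "error"
    name: str = "grid"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.isscalar(self.spacing) or self.spacing.ndim == 0:
            self.spacing = np.full(3, float(self.spacing))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.boundary not in ("clamp", "error"):
            raise ValueError("boundary must be 'clamp' or 'error'")

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.values.shape) - 1)

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def interpolate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Quadratic B-spline value(s) and gradient(s) at Cartesian points."""
        return bspline3_value_gradient(self, np.asarray(points, dtype=float))


def _bspline3_weights(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weights and derivatives of the 3-node quadratic B-spline stencil.

    ``s`` is the fractional offset from the nearest node, in [-0.5, 0.5].
    Returns (w, dw) each of shape s.shape + (3,), for nodes at offsets
    (-1, 0, +1) from the nearest node.  The weights partition unity and
    reproduce linear fields exactly.
    """
    w = np.empty(s.shape + (3,))
    dw = np.empty_like(w)
    w[..., 0] = 0.5 * (0.5 - s) ** 2
    w[..., 1] = 0.75 - s**2
    w[..., 2] = 0.5 * (0.5 + s) ** 2
    dw[..., 0] = s - 0.5
    dw[..., 1] = -2.0 * s
    dw[..., 2] = s + 0.5
    return w, dw


def bspline3_value_gradient(grid: GridPotential, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a grid and its spatial gradient with quadratic B-splines.

    points : (..., 3).  Returns (values shaped (...,), gradients (..., 3)).
    Points outside the interpolable interior (within half a spacing of
    the edge nodes) follow the grid's boundary policy: "clamp" projects
    onto the interior (gradient along clamped axes is then zero),
    "error" raises ValueError.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    squeeze = np.asarray(points).ndim == 1
    u = (pts - grid.origin) / grid.spacing  # grid coordinates
    n = np.array(grid.values.shape)

    lo = 0.5
    hi = n - 1.5
    outside = (u < lo - 1e-12) | (u > hi + 1e-12)
    clamped = np.zeros_like(u, dtype=bool)
    if outside.any():
        if grid.boundary == "error":
            bad = np.argwhere(outside.any(axis=1))[0, 0]
            raise ValueError(
                f"point {pts[bad]} outside interpolable region of grid '{grid.name}'"
            )
        clamped = outside
        u = np.clip(u, lo, hi)

    nearest = np.rint(u).astype(int)
    nearest = np.clip(nearest, 1, n - 2)
    s = u - nearest

    wx, dwx = _bspline3_weights(s[:, 0])
    wy, dwy = _bspline3_weights(s[:, 1])
    wz, dwz = _bspline3_weights(s[:, 2])

    ix = nearest[:, 0, None] + np.arange(-1, 2)
    iy = nearest[:, 1, None] + np.arange(-1, 2)
    iz = nearest[:, 2, None] + np.arange(-1, 2)
    # gather the 3x3x3 stencil: (npts, 3, 3, 3)
    cube = grid.values[
        ix[:, :, None, None], iy[:, None, :, None], iz[:, None, None, :]
    ]

    val = np.einsum("pijk,pi,pj,pk->p", cube, wx, wy, wz)
    gx = np.einsum("pijk,pi,pj,pk->p", cube, dwx, wy, wz) / grid.spacing[0]
    gy = np.einsum("pijk,pi,pj,pk->p", cube, wx, dwy, wz) / grid.spacing[1]
    gz = np.einsum("pijk,pi,pj,pk->p", cube, wx, wy, dwz) / grid.spacing[2]
    grad = np.stack([gx, gy, gz], axis=-1)
    grad[clamped] = 0.0

    if squeeze:
        return val[0], grad[0]
    return val, grad


# ---------------------------------------------------------------------------
# OpenDX scalar-field format


def write_dx(grid: GridPotential, path: str | Path, comment: str = "") -> None:
    """Write a grid as an OpenDX regular scalar field (text)."""
    nx, ny, nz = grid.values.shape
    lines = []
    if comment:
        for ln in comment.splitlines():
            lines.append(f"# {ln}")
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append("origin {:.17g} {:.17g} {:.17g}".format(*grid.origin))
    lines.append(f"delta {grid.spacing[0]:.17g} 0 0")
    lines.append(f"delta 0 {grid.spacing[1]:.17g} 0")
    lines.append(f"delta 0 0 {grid.spacing[2]:.17g}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows"
    )
    flat = grid.values.reshape(-1)  # C order: z varies fastest (DX convention)
    for i in range(0, flat.size, 3):
        chunk = flat[i : i + 3]
        lines.append(" ".join(f"{v:.17g}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path, boundary: str = "error") -> GridPotential:
    """Read an OpenDX regular scalar field written by :func:`write_dx`."""
    counts = origin = None
    deltas = []
    data: list[float] = []
    n_items = 0
    reading = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if reading and len(data) < n_items:
            data.extend(float(t) for t in line.split())
            continue
        if line.startswith("object 1"):
            counts = tuple(int(t) for t in line.split()[-3:])
        elif line.startswith("origin"):
            origin = np.array([float(t) for t in line.split()[1:4]])
        elif line.startswith("delta"):
            deltas.append([float(t) for t in line.split()[1:4]])
        elif "data follows" in line:
            n_items = int(line.split()[-3])
            reading = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular OpenDX scalar field")
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    values = np.array(data[:n_items]).reshape(counts)
    return GridPotential(origin=origin, spacing=spacing, values=values, boundary=boundary, name=Path(path).stem)
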