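"""Fence construction: steric rods, charged rods, and protein filaments.

Three fence families guard the corral boundary (the line X = 0, running
along Y):

* steric rods -- contact-spaced uncharged impenetrable spheres on the
  diffusion plane with a single centered gap of length ``L_open``;
* electrostatic rods -- an unbroken row of charged spheres raised a
  height ``h`` above the diffusion plane (no steric core, so only the
  electrostatic map acts);
* protein filaments -- rigid atomic structures replicated helically
  along the fence axis and buried to a depth ``Z_min`` below the lipid
  phosphate plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RodFenceSpec",
    "FilamentPlacement",
    "FenceAtoms",
    "build_steric_rod",
    "build_electrostatic_rod",
    "replicate_filament",
    "bury_filament",
    "load_structure",
    "write_structure",
    "RESIDUE_FORMAL_CHARGE",
    "ELEMENT_RADII",
]

#: Formal charges per residue at neutral pH (HIS neutral by default).
RESIDUE_FORMAL_CHARGE: dict[str, float] = {
    "ASP": -1.0,
    "GLU": -1.0,
    "LYS": +1.0,
    "ARG": +1.0,
    "HIS": 0.0,
}

CHARGED_RESIDUES = ("ASP", "GLU", "LYS", "ARG")

#: Residue names accepted by the PDB loader (neutral unless in the
#: formal-charge table); "ROD" marks fence spheres, "UNK" placeholders.
KNOWN_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL HSD HSE HSP ROD UNK".split()
)

#: Fallback van der Waals-like radii per element (A).
ELEMENT_RADII: dict[str, float] = {
    "H": 1.00,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "X": 2.00,
}


@dataclass(frozen=True)
class RodFenceSpec:
    """Geometry and charge of a rod-like fence along Y at X = 0.

    fence_length L and opening_length L_open in A; sphere_charge q in e
    per sphere; height h in A above the diffusion plane.  Steric rods
    have q = 0, h = 0; electrostatic rods have L_open = 0 and h > 0.
    """

    fence_length: float = 1000.0
    opening_length: float = 0.0
    sphere_charge: float = 0.0
    height: float = 0.0
    sphere_radius: float = 5.4
    sphere_spacing: float = 10.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.opening_length <= self.fence_length):
            raise ValueError("opening length must lie in [0, fence length]")
        if self.sphere_radius <= 0 or self.sphere_spacing <= 0:
            raise ValueError("sphere radius and spacing must be positive")
        if self.height < 0:
            raise ValueError("height must be non-negative")


@dataclass
class FenceAtoms:
    """Coordinates plus per-atom attributes of a built fence."""

    coords: np.ndarray  # (n, 3) A, simulation frame unless noted
    charges: np.ndarray  # (n,) e
    radii: np.ndarray  # (n,) A
    residues: list[str] = field(default_factory=list)
    steric: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if not self.residues:
            self.residues = ["UNK"] * len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


def build_steric_rod(spec: RodFenceSpec, plane_z: float = 0.0) -> FenceAtoms:
    """Uncharged blocking spheres along Y at X=0 with one centered gap.

    The gap of length ``L_open`` is centered at Y = 0; the blocked
    segments cover the remainder of [-L/2, L/2] with contact-spaced
    spheres.  ``L_open == L`` returns an empty fence (free diffusion).
    """
    if spec.sphere_charge != 0 or spec.height != 0:
        raise ValueError("steric rods are uncharged and sit on the plane")
    L = spec.fence_length
    half_gap = spec.opening_length / 2.0
    if spec.opening_length <= 1e-9:
        segments = ((-L / 2.0, L / 2.0),)
    else:
        segments = ((-L / 2.0, -half_gap), (half_gap, L / 2.0))
    ys: list[float] = []
    for lo, hi in segments:
        seg = hi - lo
        if seg <= 1e-9:
            continue
        n = max(1, math.ceil(seg / spec.sphere_spacing))
        if n == 1:
            ys.append(0.5 * (lo + hi))
        else:
            step = (seg - spec.sphere_spacing) / (n - 1)
            start = lo + spec.sphere_spacing / 2.0
            ys.extend(start + step * i for i in range(n))
    ys_arr = np.array(sorted(ys))
    coords = np.column_stack(
        [np.zeros_like(ys_arr), ys_arr, np.full_like(ys_arr, plane_z)]
    )
    return FenceAtoms(
        coords=coords,
        charges=np.zeros(len(ys_arr)),
        radii=np.full(len(ys_arr), spec.sphere_radius),
        residues=["ROD"] * len(ys_arr),
        steric=True,
    )


def build_electrostatic_rod(spec: RodFenceSpec, plane_z: float = 0.0) -> FenceAtoms:
    """Unbroken charged row at height ``h`` above the diffusion plane.

    Raised off the plane to eliminate steric interactions; the fence
    therefore contributes only to the electrostatic map (steric=False).
    """
    if spec.opening_length != 0:
        raise ValueError("electrostatic rods have no opening")
    n = max(1, math.ceil(spec.fence_length / spec.sphere_spacing))
    # center one sphere at Y=0 so the row is symmetric about the origin
    half = (n - 1) / 2.0
    ys = (np.arange(n) - half) * spec.sphere_spacing
    z = plane_z + spec.height
    coords = np.column_stack([np.zeros(n), ys, np.full(n, z)])
    return FenceAtoms(
        coords=coords,
        charges=np.full(n, spec.sphere_charge),
        radii=np.full(n, spec.sphere_radius),
        residues=["ROD"] * n,
        steric=False,
    )


@dataclass(frozen=True)
class FilamentPlacement:
    """Helical replication parameters of a filament fence.

    Subunit i is rotated by i*rotation_per_subunit about the fence (Y)
    axis and translated i*translation_per_subunit along it.  The actin
    fence uses 166.4 deg / 27.6 A per monomer; the human and yeast
    septin fences use pure translations of 253.2 A and 338.7 A per
    biological unit.
    """

    rotation_per_subunit: float = 0.0  # degrees
    translation_per_subunit: float = 27.6  # A along Y
    n_subunits: int = 1

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("need at least one subunit")


def replicate_filament(atoms: FenceAtoms, placement: FilamentPlacement) -> FenceAtoms:
    """Replicate a monomer helically along the fence (Y) axis."""
    if atoms.n_atoms == 0:
        raise ValueError("monomer has no atoms")
    coords_out = []
    res_out: list[str] = []
    theta0 = math.radians(placement.rotation_per_subunit)
    for i in range(placement.n_subunits):
        th = theta0 * i
        c, s = math.cos(th), math.sin(th)
        # rotation about the Y axis
        rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        xyz = atoms.coords @ rot.T
        xyz[:, 1] += placement.translation_per_subunit * i
        coords_out.append(xyz)
        res_out.extend(atoms.residues)
    n = placement.n_subunits
    return FenceAtoms(
        coords=np.vstack(coords_out),
        charges=np.tile(atoms.charges, n),
        radii=np.tile(atoms.radii, n),
        residues=res_out,
        steric=atoms.steric,
    )


def bury_filament(atoms: FenceAtoms, z_min: float) -> FenceAtoms:
    """Translate in Z so the lowest atom sits at ``z_min``.

    ``z_min`` is given in the phosphate-plane frame (Z = 0 at the lipid
    phosphates); negative values bury the filament into the membrane.
    X and Y are unchanged; the operation is idempotent.
    """
    coords = atoms.coords.copy()
    coords[:, 2] += z_min - coords[:, 2].min()
    return FenceAtoms(
        coords=coords,
        charges=atoms.charges.copy(),
        radii=atoms.radii.copy(),
        residues=list(atoms.residues),
        steric=atoms.steric,
    )


# ---------------------------------------------------------------------------
# PDB input/output (Biopython)


def load_structure(
    path: str | Path,
    charge_table: dict[str, float] | None = None,
    radius_table: dict[str, float] | None = None,
    strict: bool = True,
) -> FenceAtoms:
    """Load a PDB file into fence atoms with formal charges and radii.

    One charge per residue (placed on the first atom of charged
    residues), radii per element; unknown elements fall back to the
    generic radius.  With ``strict`` (default) residues outside the
    known set raise a ValueError naming every offender.
    """
    from Bio.PDB import PDBParser

    charge_table = dict(RESIDUE_FORMAL_CHARGE if charge_table is None else charge_table)
    radius_table = dict(ELEMENT_RADII if radius_table is None else radius_table)

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("fence", str(path))
    coords, charges, radii, residues = [], [], [], []
    unknown: set[str] = set()
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                if resname not in KNOWN_RESIDUES and resname not in charge_table:
                    unknown.add(resname)
                q_res = charge_table.get(resname, 0.0)
                for k, atom in enumerate(residue):
                    coords.append(atom.coord.astype(float))
                    if resname == "ROD":
                        # rod spheres round-trip their charge via B-factor
                        charges.append(float(atom.bfactor))
                    else:
                        charges.append(q_res if k == 0 else 0.0)
                    elem = (atom.element or atom.get_name()[:1]).strip().upper()
                    radii.append(radius_table.get(elem, radius_table.get("X", 2.0)))
                    residues.append(resname)
        break  # first model only
    if not coords:
        raise ValueError(f"{path}: no atoms parsed")
    if strict and unknown:
        raise ValueError(
            f"{path}: unknown residues {sorted(unknown)}; extend the charge "
            "table or pass strict=False"
        )
    return FenceAtoms(
        coords=np.array(coords),
        charges=np.array(charges),
        radii=np.array(radii),
        residues=residues,
    )


def write_structure(atoms: FenceAtoms, path: str | Path, bead_element: str = "C") -> None:
    """Write fence atoms as a minimal PDB file (one atom per record).

    Rod spheres (residue "ROD") carry their per-atom charge in the
    B-factor column so charged rods survive a PDB round trip; for all
    other residues charges are reassigned from the residue table on
    loading.
    """
    lines = []
    for i, (xyz, res, q) in enumerate(
        zip(atoms.coords, atoms.residues, atoms.charges), start=1
    ):
        serial = i % 100000
        resseq = ((i - 1) % 9999) + 1
        bfac = q if res == "ROD" else 0.0
        lines.append(
            f"ATOM  {serial:5d} {bead_element + 'A':<4s}{res:>4s} A{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00{bfac:6.2f}          "
            f"{bead_element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
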