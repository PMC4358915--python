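"""Fence construction tests: rods, filament replication, burial, PDB I/O."""

import numpy as np
import pytest

from corralsim import (
    FenceAtoms,
    FilamentPlacement,
    RodFenceSpec,
    build_electrostatic_rod,
    build_steric_rod,
    bury_filament,
    load_structure,
    replicate_filament,
    write_structure,
)


class TestStericRod:
    def test_fully_open_fence_is_empty(self):
        rod = build_steric_rod(RodFenceSpec(fence_length=1000, opening_length=1000))
        assert rod.n_atoms == 0

    def test_unbroken_rod_sphere_count(self):
        rod = build_steric_rod(RodFenceSpec(fence_length=1000, opening_length=0))
        assert rod.n_atoms == 93  # ceil(1000 / 10.8) contact-spaced spheres
        assert np.all(rod.charges == 0)
        assert np.all(rod.coords[:, 0] == 0) and np.all(rod.coords[:, 2] == 0)

    def test_centered_gap_leaves_two_end_segments(self):
        rod = build_steric_rod(RodFenceSpec(fence_length=1000, opening_length=500))
        y = rod.coords[:, 1]
        assert np.all((np.abs(y) >= 250 - 5.4) & (np.abs(y) <= 500))
        assert (y < 0).sum() == (y > 0).sum()

    @pytest.mark.parametrize("l_open", [0, 20, 100, 500])
    def test_blocked_length_complements_opening(self, l_open):
        """Sphere coverage spans exactly the non-gap segments."""
        spec = RodFenceSpec(fence_length=1000, opening_length=l_open)
        rod = build_steric_rod(spec)
        y = np.sort(rod.coords[:, 1])
        # spheres stay off the gap and inside the fence
        if l_open:
            assert np.all(np.abs(y) >= l_open / 2)
        assert np.all(np.abs(y) <= 500)
        # consecutive spheres never leave a passable hole (> contact spacing)
        gaps = np.diff(y)
        interior = gaps[gaps < l_open - 1e-9] if l_open else gaps
        assert np.all(interior <= spec.sphere_spacing + 1e-9)

    def test_opening_larger_than_fence_rejected(self):
        with pytest.raises(ValueError):
            RodFenceSpec(fence_length=1000, opening_length=1001)


class TestElectrostaticRod:
    def test_row_is_unbroken_and_raised(self):
        rod = build_electrostatic_rod(
            RodFenceSpec(fence_length=1000, sphere_charge=-1.0, height=7.0)
        )
        assert rod.n_atoms == 93
        assert np.all(rod.coords[:, 2] == 7.0)
        assert np.all(rod.charges == -1.0)
        assert rod.steric is False  # raised to eliminate steric interactions

    def test_neutral_rod_carries_no_charge(self):
        rod = build_electrostatic_rod(RodFenceSpec(sphere_charge=0.0, height=5.0))
        assert rod.net_charge == 0.0

    def test_symmetric_about_y_origin(self):
        rod = build_electrostatic_rod(RodFenceSpec(sphere_charge=0.5, height=2.0))
        y = np.sort(rod.coords[:, 1])
        assert np.allclose(y + y[::-1], 0.0, atol=1e-9)


def bead_monomer():
    rng = np.random.default_rng(7)
    coords = rng.uniform(-5, 5, size=(12, 3))
    return FenceAtoms(
        coords=coords,
        charges=np.zeros(12),
        radii=np.full(12, 2.0),
        residues=["GLY"] * 12,
    )


class TestFilamentReplication:
    def test_single_subunit_is_identity(self):
        mono = bead_monomer()
        rep = replicate_filament(mono, FilamentPlacement(n_subunits=1))
        assert np.allclose(rep.coords, mono.coords)

    def test_actin_parameters_accumulate(self):
        """13 subunits at 27.6 A rise span 12 * 27.6 = 331.2 A of offsets."""
        mono = bead_monomer()
        rep = replicate_filament(
            mono,
            FilamentPlacement(rotation_per_subunit=166.4, translation_per_subunit=27.6,
                              n_subunits=13),
        )
        assert rep.n_atoms == 13 * mono.n_atoms
        y_shift = rep.coords[-mono.n_atoms:, 1] - mono.coords[:, 1]
        assert np.allclose(y_shift, 12 * 27.6)
        # 13 * 166.4 deg = 2163.2 deg: 3.2 deg past six full turns
        last = rep.coords[-mono.n_atoms:] - np.array([0, 12 * 27.6, 0])
        th = np.radians(12 * 166.4)
        rot = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]])
        assert np.allclose(last, mono.coords @ rot.T, atol=1e-9)

    def test_rigidity_preserves_internal_distances(self):
        mono = bead_monomer()
        rep = replicate_filament(
            mono, FilamentPlacement(rotation_per_subunit=166.4, translation_per_subunit=27.6, n_subunits=5)
        )
        d0 = np.linalg.norm(mono.coords[:, None] - mono.coords[None, :], axis=-1)
        for i in range(5):
            sub = rep.coords[i * 12 : (i + 1) * 12]
            d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
            assert np.allclose(d, d0, atol=1e-10)

    def test_replication_commutes_with_axis_translation(self):
        mono = bead_monomer()
        placement = FilamentPlacement(rotation_per_subunit=90.0, translation_per_subunit=30.0, n_subunits=4)
        shifted = FenceAtoms(
            coords=mono.coords + np.array([0.0, 11.0, 0.0]),
            charges=mono.charges, radii=mono.radii, residues=list(mono.residues),
        )
        a = replicate_filament(shifted, placement).coords
        b = replicate_filament(mono, placement).coords + np.array([0.0, 11.0, 0.0])
        assert np.allclose(a, b, atol=1e-10)


class TestBurial:
    def test_touching_the_phosphate_plane(self):
        mono = bead_monomer()
        buried = bury_filament(mono, 0.0)
        assert buried.coords[:, 2].min() == pytest.approx(0.0)

    def test_uniform_shift(self):
        mono = bead_monomer()
        zmin0 = mono.coords[:, 2].min()
        buried = bury_filament(mono, -9.0)
        assert np.allclose(buried.coords[:, 2] - mono.coords[:, 2], -9.0 - zmin0)
        assert np.allclose(buried.coords[:, :2], mono.coords[:, :2])

    def test_idempotent(self):
        mono = bead_monomer()
        once = bury_filament(mono, -12.0)
        twice = bury_filament(once, -12.0)
        assert np.allclose(once.coords, twice.coords)

    @pytest.mark.parametrize("zmin", [0.0, -5.0, -10.0, -15.0])
    def test_recovers_requested_depth(self, zmin):
        buried = bury_filament(bead_monomer(), zmin)
        assert buried.coords[:, 2].min() == pytest.approx(zmin)


PDB_FIXTURE = """\
ATOM      1  N   LYS A   1       0.000   0.000   5.000  1.00  0.00           N
ATOM      2  CA  LYS A   1       1.400   0.000   5.000  1.00  0.00           C
ATOM      3  CB  ASP A   2       3.000   1.000   4.000  1.00  0.00           C
ATOM      4  OD1 ASP A   2       3.500   1.200   4.100  1.00  0.00           O
ATOM      5  CB  ASP A   3       5.000  -1.000   4.000  1.00  0.00           C
ATOM      6  CZ  ARG A   4       7.123   2.456  -3.789  1.00  0.00           C
END
"""


class TestPDBIO:
    def test_formal_charges_from_residue_table(self, tmp_path):
        p = tmp_path / "fixture.pdb"
        p.write_text(PDB_FIXTURE)
        atoms = load_structure(p)
        assert atoms.n_atoms == 6
        # +1 (LYS) - 1 (ASP) - 1 (ASP) + 1 (ARG) = 0; per-residue net:
        assert atoms.net_charge == pytest.approx(0.0)
        lys_total = atoms.charges[:2].sum()
        assert lys_total == pytest.approx(+1.0)

    def test_round_trip_coordinates_to_pdb_precision(self, tmp_path):
        p = tmp_path / "fixture.pdb"
        p.write_text(PDB_FIXTURE)
        atoms = load_structure(p)
        out = tmp_path / "copy.pdb"
        write_structure(atoms, out)
        atoms2 = load_structure(out)
        assert np.allclose(atoms.coords, atoms2.coords, atol=1e-3)
        assert atoms.residues == atoms2.residues

    def test_element_radii_assigned(self, tmp_path):
        p = tmp_path / "fixture.pdb"
        p.write_text(PDB_FIXTURE)
        atoms = load_structure(p)
        assert atoms.radii[0] == pytest.approx(1.55)  # N
        assert atoms.radii[1] == pytest.approx(1.70)  # C

    def test_unparseable_file_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER nothing\nEND\n")
        with pytest.raises(ValueError):
            load_structure(p)
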