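"""Unit tests for structure generation, PDB ingestion and voxelization."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from spisim import (
    Composition,
    VIRUS_LIKE,
    make_icosahedral_particle,
    make_toy_protein,
    read_pdb,
    structure_to_density,
)
from spisim.synthetic_structures import (
    MIN_INTERATOMIC_NM,
    MolecularStructure,
    VoxelDensity,
    read_density_h5,
    write_density_h5,
    write_xyz,
)

def pdb_line(serial, name, res, seq, xyz, element, occ=1.0, altloc=" ", record="ATOM"):
    """Format one fixed-width ATOM/HETATM record."""
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{res:<3s} A{seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


PDB_ATOM = pdb_line(1, " CA", "ALA", 1, (1.0, 2.0, 3.0), "C")


class TestToyProtein:
    def test_atom_count_follows_residue_multiset(self):
        # 15 atoms per residue {C:5, N:1, O:1, H:8}, one S per 30 residues
        assert make_toy_protein(10, seed=1).n_atoms == 150
        s = make_toy_protein(30, seed=1)
        assert s.n_atoms == 451
        assert np.sum(s.elements == "S") == 1
        counts = {el: int(np.sum(s.elements == el)) for el in "CNOH"}
        assert counts == {"C": 150, "N": 30, "O": 30, "H": 240}

    def test_seed_determinism(self):
        a = make_toy_protein(10, seed=1)
        b = make_toy_protein(10, seed=1)
        assert np.array_equal(a.positions, b.positions)
        c = make_toy_protein(10, seed=2)
        assert not np.array_equal(a.positions, c.positions)

    def test_geometry_bounds(self):
        # brute-force pairwise distances and radius of gyration
        s = make_toy_protein(100, seed=7)
        assert pdist(s.positions).min() >= MIN_INTERATOMIC_NM
        assert 0.8 <= s.radius_of_gyration() <= 3.0

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValueError):
            make_toy_protein(0, seed=1)


class TestStructureInvariants:
    def test_rejects_overlapping_atoms(self):
        with pytest.raises(ValueError, match="closer"):
            MolecularStructure(
                np.array(["C", "C"]),
                np.array([[0.0, 0.0, 0.0], [0.01, 0.0, 0.0]]),
                np.array([12.011, 12.011]),
            )

    def test_rejects_bad_mass(self):
        with pytest.raises(ValueError, match="mass"):
            MolecularStructure(
                np.array(["C"]), np.zeros((1, 3)), np.array([14.0])
            )


class TestIcosahedralParticle:
    def test_500nm_particle_fits_bounding_box(self):
        vd = make_icosahedral_particle(500.0, VIRUS_LIKE, 10.0)
        occupied = np.nonzero(vd.grid > 0)
        for ax in range(3):
            extent = (occupied[ax].max() - occupied[ax].min() + 1) * vd.voxel_size
            assert extent <= 500.0 + 2 * vd.voxel_size
        # interior voxels carry the uniform density
        interior = VIRUS_LIKE.electron_density_nm3() * vd.voxel_size**3
        assert vd.grid.max() == pytest.approx(interior, rel=1e-6)

    def test_sphere_mode_matches_closed_form_volume(self):
        d = 200.0
        vd = make_icosahedral_particle(d, VIRUS_LIKE, 4.0, shape="sphere")
        exact = VIRUS_LIKE.electron_density_nm3() * math.pi / 6.0 * d**3
        assert vd.total_electrons == pytest.approx(exact, rel=0.02)

    def test_icosahedron_volume_converges(self):
        # circumradius R: V = (5/12)(3+sqrt5) a^3 with a = R * 4/sqrt(10+2*sqrt5)
        d = 200.0
        R = d / 2
        a = 4.0 * R / math.sqrt(10.0 + 2.0 * math.sqrt(5.0))
        exact = VIRUS_LIKE.electron_density_nm3() * (5.0 / 12.0) * (3 + math.sqrt(5)) * a**3
        errors = []
        for voxel in (8.0, 4.0):
            vd = make_icosahedral_particle(d, VIRUS_LIKE, voxel)
            errors.append(abs(vd.total_electrons - exact) / exact)
        assert errors[-1] < 0.02
        assert errors[-1] <= errors[0]

    def test_coarse_voxel_rejected(self):
        with pytest.raises(ValueError, match="voxel"):
            make_icosahedral_particle(500.0, VIRUS_LIKE, 60.0)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            Composition({}, 1.0)


class TestReadPdb:
    def test_single_atom_angstrom_to_nm(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(PDB_ATOM + "END\n")
        s = read_pdb(path)
        assert s.n_atoms == 1
        assert s.elements[0] == "C"
        np.testing.assert_allclose(s.positions[0], [0.1, 0.2, 0.3])

    def test_altloc_takes_highest_occupancy(self, tmp_path):
        lines = pdb_line(1, " CA", "ALA", 1, (1.0, 2.0, 3.0), "C", occ=0.6, altloc="A") + \
            pdb_line(2, " CA", "ALA", 1, (9.0, 9.0, 9.0), "C", occ=0.4, altloc="B")
        path = tmp_path / "altloc.pdb"
        path.write_text(lines + "END\n")
        s = read_pdb(path)
        assert s.n_atoms == 1
        np.testing.assert_allclose(s.positions[0], [0.1, 0.2, 0.3])

    def test_waters_dropped_by_default(self, tmp_path):
        lines = (
            pdb_line(1, " CA", "ALA", 1, (1.0, 2.0, 3.0), "C")
            + pdb_line(2, " N", "ALA", 1, (4.0, 2.0, 3.0), "N")
            + pdb_line(3, " O", "ALA", 1, (1.0, 5.0, 3.0), "O")
            + pdb_line(4, " O", "HOH", 2, (11.0, 2.0, 3.0), "O", record="HETATM")
            + pdb_line(5, " O", "HOH", 3, (15.0, 2.0, 3.0), "O", record="HETATM")
        )
        path = tmp_path / "wat.pdb"
        path.write_text(lines + "END\n")
        assert read_pdb(path).n_atoms == 3
        assert read_pdb(path, keep_waters=True).n_atoms == 5

    def test_unknown_element_skipped_with_warning(self, tmp_path):
        lines = PDB_ATOM + pdb_line(
            2, "FE", "HEM", 2, (8.0, 2.0, 3.0), "FE", record="HETATM"
        )
        path = tmp_path / "fe.pdb"
        path.write_text(lines + "END\n")
        with pytest.warns(UserWarning, match="Fe"):
            s = read_pdb(path)
        assert s.n_atoms == 1

    def test_no_atoms_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError):
            read_pdb(path)


class TestStructureToDensity:
    def test_single_carbon_deposits_six_electrons(self):
        s = MolecularStructure(np.array(["C"]), np.zeros((1, 3)), np.array([12.011]))
        vd = structure_to_density(s, 0.5)
        assert vd.total_electrons == 6.0
        assert np.sum(vd.grid > 0) == 1

    def test_electron_conservation_exact(self, toy100):
        vd = structure_to_density(toy100, 0.3)
        assert vd.total_electrons == float(toy100.atomic_numbers.sum())

    def test_same_voxel_additivity(self):
        s = MolecularStructure(
            np.array(["C", "O"]),
            np.array([[0.0, 0.0, 0.0], [0.06, 0.0, 0.0]]),
            np.array([12.011, 15.999]),
        )
        vd = structure_to_density(s, 1.0)
        assert vd.grid.max() == 14.0


class TestIO:
    def test_xyz_write(self, tmp_path):
        s = make_toy_protein(2, seed=3)
        path = tmp_path / "s.xyz"
        write_xyz(s, path)
        lines = path.read_text().splitlines()
        assert int(lines[0]) == s.n_atoms
        assert len(lines) == s.n_atoms + 2

    def test_density_h5_round_trip(self, tmp_path):
        vd = make_icosahedral_particle(100.0, VIRUS_LIKE, 5.0)
        path = tmp_path / "d.h5"
        write_density_h5(vd, path)
        back = read_density_h5(path)
        np.testing.assert_array_equal(back.grid, vd.grid)
        assert back.voxel_size == vd.voxel_size

    def test_voxel_density_invariants(self):
        with pytest.raises(ValueError):
            VoxelDensity(np.full((2, 2, 2), -1.0), 1.0)
        with pytest.raises(ValueError):
            VoxelDensity(np.ones((1, 2, 2)), 1.0)
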