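"""Structure I/O, residue geometry, and the synthetic-fixture generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duores.errors import PDBParseError, StructureError
from duores.structures import (
    Atom, Residue, make_toy_complex, read_pdb, residue_geometry, write_pdb,
)


def _atom(name, element, mass, pos):
    return Atom(name=name, element=element, mass=mass, charge=0.0,
                position=np.asarray(pos, dtype=float))


# ---------------------------------------------------------------------------
# residue geometry
# ---------------------------------------------------------------------------

def test_point_mass_has_zero_radius_of_gyration():
    res = Residue(1, "GLY", [_atom("CA", "C", 12.011, (1.0, 2.0, 3.0))], 0)
    com, rg = residue_geometry(res)
    assert np.allclose(com, [1.0, 2.0, 3.0])
    assert rg == pytest.approx(0.0, abs=1e-12)


def test_two_equal_masses_give_midpoint_com_and_half_spacing_rg():
    res = Residue(1, "X", [_atom("A", "C", 12.0, (0, 0, 0)),
                           _atom("B", "C", 12.0, (1, 0, 0))], None)
    com, rg = residue_geometry(res)
    assert np.allclose(com, [0.5, 0.0, 0.0])
    assert np.isclose(rg, 0.5)


def test_geometry_matches_direct_summation_oracle(rng):
    masses = rng.uniform(1.0, 16.0, size=4)
    pos = rng.normal(size=(4, 3))
    res = Residue(1, "X", [
        _atom(f"A{i}", "C", masses[i], pos[i]) for i in range(4)
    ], None)
    com, rg = residue_geometry(res)
    com_oracle = sum(m * p for m, p in zip(masses, pos)) / masses.sum()
    rg_oracle = np.sqrt(
        sum(m * np.dot(p - com_oracle, p - com_oracle)
            for m, p in zip(masses, pos)) / masses.sum()
    )
    assert np.allclose(com, com_oracle)
    assert np.isclose(rg, rg_oracle)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=3, max_size=3))
def test_geometry_invariant_under_translation(shift):
    rng = np.random.default_rng(7)
    pos = rng.normal(size=(5, 3))
    masses = rng.uniform(1.0, 20.0, size=5)

    def make(offset):
        return Residue(1, "X", [
            _atom(f"A{i}", "C", masses[i], pos[i] + offset) for i in range(5)
        ], None)

    com0, rg0 = residue_geometry(make(np.zeros(3)))
    com1, rg1 = residue_geometry(make(np.asarray(shift)))
    assert np.allclose(com1 - com0, shift, atol=1e-12)
    assert np.isclose(rg0, rg1, atol=1e-12)


def test_radius_of_gyration_invariant_under_rotation(rng):
    from scipy.spatial.transform import Rotation

    pos = rng.normal(size=(6, 3))
    masses = rng.uniform(1.0, 20.0, size=6)
    rot = Rotation.random(random_state=11).as_matrix()
    res = Residue(1, "X", [_atom(f"A{i}", "C", masses[i], pos[i])
                           for i in range(6)], None)
    res_rot = Residue(1, "X", [_atom(f"A{i}", "C", masses[i], pos[i] @ rot.T)
                               for i in range(6)], None)
    assert np.isclose(residue_geometry(res)[1], residue_geometry(res_rot)[1])


def test_empty_residue_is_rejected():
    with pytest.raises(StructureError):
        residue_geometry(Residue(1, "X", [], None))


def test_atoms_reject_nonpositive_mass_and_bad_positions():
    with pytest.raises(StructureError):
        _atom("A", "C", 0.0, (0, 0, 0))
    with pytest.raises(StructureError):
        _atom("A", "C", 12.0, (0, 0, np.nan))


# ---------------------------------------------------------------------------
# fixture generator
# ---------------------------------------------------------------------------

def test_toy_complex_is_deterministic_for_fixed_seed():
    a = make_toy_complex(10, seed=1)
    b = make_toy_complex(10, seed=1)
    assert a.n_residues == b.n_residues == 10
    for ra, rb in zip(a.residues, b.residues):
        assert len(ra.atoms) == len(rb.atoms)
        assert np.array_equal(ra.positions(), rb.positions())
    assert np.array_equal(a.ligand_positions(), b.ligand_positions())


def test_toy_complex_seed_sensitivity():
    a = make_toy_complex(10, seed=1)
    b = make_toy_complex(10, seed=2)
    assert not np.allclose(a.calpha_positions(), b.calpha_positions())


def test_toy_calpha_spacing_within_ten_percent_of_canonical():
    for seed in (1, 2, 3):
        s = make_toy_complex(12, seed=seed)
        ca = s.calpha_positions()
        spacing = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(spacing >= 0.342)
        assert np.all(spacing <= 0.418)


def test_toy_satellite_and_ligand_counts_in_declared_ranges():
    s = make_toy_complex(15, seed=4)
    for res in s.residues:
        # one C-alpha plus 3..8 satellites
        assert 4 <= len(res.atoms) <= 9
        assert res.calpha.name == "CA"
    assert 5 <= len(s.ligand) <= 20


def test_toy_ligand_sits_near_the_pocket_residue():
    s = make_toy_complex(15, seed=4, pocket_residue=8)
    pocket_ca = s.residues[7].calpha.position
    d = np.linalg.norm(s.ligand_positions() - pocket_ca, axis=1)
    assert d.min() <= 0.5


def test_toy_complex_rejects_too_few_residues():
    with pytest.raises(ValueError):
        make_toy_complex(2, seed=1)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def test_pdb_round_trip_preserves_coordinates_to_pdb_precision(tmp_path, toy):
    path = tmp_path / "toy.pdb"
    write_pdb(toy, path)
    back = read_pdb(path, {"LIG"})
    assert back.n_residues == toy.n_residues
    assert len(back.ligand) == len(toy.ligand)
    # PDB stores 3 decimals in Angstrom = 1e-4 nm resolution
    for orig, rt in zip(toy.residues, back.residues):
        assert np.allclose(orig.positions(), rt.positions(), atol=1.01e-4)
    assert np.allclose(toy.ligand_positions(), back.ligand_positions(),
                       atol=1.01e-4)


def test_read_pdb_converts_angstrom_to_nm(tmp_path, toy):
    path = tmp_path / "toy.pdb"
    write_pdb(toy, path)
    ca = read_pdb(path).calpha_positions()
    spacing = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    # consecutive C-alpha spacing ~0.38 nm, not ~3.8
    assert np.all((spacing > 0.3) & (spacing < 0.5))


def test_read_pdb_separates_ligand_by_residue_name(tmp_path, toy):
    path = tmp_path / "toy.pdb"
    write_pdb(toy, path, ligand_resname="ABC")
    s = read_pdb(path, {"ABC"})
    assert len(s.ligand) == len(toy.ligand)
    # unmatched selector leaves the HETATM residue as a plain (non-aa) residue
    s2 = read_pdb(path, {"ZZZ"})
    assert len(s2.ligand) == 0
    assert s2.n_residues == toy.n_residues + 1


def test_truncated_atom_line_raises_parse_error(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text(
        "ATOM      1  CA  GLY A   1       1.000   2.000\n"
        "END\n"
    )
    with pytest.raises(PDBParseError):
        read_pdb(bad)


def test_amino_acid_without_calpha_raises_structure_error(tmp_path):
    bad = tmp_path / "noca.pdb"
    bad.write_text(
        "ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00"
        "           N\n"
        "ATOM      2  C   GLY A   1       2.000   2.000   3.000  1.00  0.00"
        "           C\n"
        "END\n"
    )
    with pytest.raises(StructureError):
        read_pdb(bad)


def test_waters_are_dropped_on_read(tmp_path, toy):
    path = tmp_path / "wet.pdb"
    write_pdb(toy, path)
    lines = path.read_text().splitlines()
    water = ("HETATM 9000  O   HOH A 900       9.000   9.000   9.000  1.00"
             "  0.00           O")
    lines.insert(-1, water)
    path.write_text("\n".join(lines) + "\n")
    s = read_pdb(path)
    assert all(r.name != "HOH" for r in s.residues)
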