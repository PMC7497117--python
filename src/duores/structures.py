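"""Protein–ligand structures: PDB I/O, residue geometry, synthetic fixtures.

Internal length unit is the nanometre; PDB files (Ångström) are converted on
read and write.  Only single-model, effectively single-chain PDBs are
supported; if several MODEL records are present the first one is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.PDB.Polypeptide import is_aa

from .errors import LigandMissingError, PDBParseError, StructureError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_pdb",
    "write_pdb",
    "residue_geometry",
    "make_toy_complex",
]

ANGSTROM_PER_NM = 10.0

# fallback masses (amu) when the element column is absent or unknown
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845,
}


@dataclass
class Atom:
    """A point particle with mass (amu), partial charge (e) and position (nm)."""

    name: str
    element: str
    mass: float
    charge: float
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise StructureError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: non-finite position")
        if self.mass <= 0:
            raise StructureError(f"atom {self.name}: non-positive mass {self.mass}")


@dataclass
class Residue:
    """A residue: 1-based index, name, atoms, and the C-alpha atom index.

    ``calpha_index`` is ``None`` only for non-amino-acid entities.
    """

    index: int
    name: str
    atoms: list[Atom]
    calpha_index: int | None = None

    @property
    def calpha(self) -> Atom:
        if self.calpha_index is None:
            raise StructureError(f"residue {self.name} {self.index} has no C-alpha")
        return self.atoms[self.calpha_index]

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


@dataclass
class Structure:
    """A protein (list of residues) plus an optional ligand, in a box (nm)."""

    residues: list[Residue]
    ligand: list[Atom] = field(default_factory=list)
    box: np.ndarray | None = None

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def calpha_positions(self, indices=None) -> np.ndarray:
        """C-alpha coordinates (nm) for the given residue indices (1-based)."""
        residues = self.residues if indices is None else [
            self.residues[i - 1] for i in indices
        ]
        return np.array([r.calpha.position for r in residues])

    def ligand_positions(self) -> np.ndarray:
        if not self.ligand:
            raise LigandMissingError("structure has no ligand")
        return np.array([a.position for a in self.ligand])

    def require_ligand(self) -> None:
        if not self.ligand:
            raise LigandMissingError(
                "this operation needs a ligand; none was flagged on read"
            )


def _element_mass(element: str, name: str) -> float:
    key = element.strip().upper() or name.strip()[:1].upper()
    try:
        return _ELEMENT_MASSES[key]
    except KeyError:
        raise StructureError(f"unknown element {element!r} for atom {name!r}") from None


def read_pdb(path, ligand_selector=frozenset({"LIG"})) -> Structure:
    """Read a protein–ligand complex from a PDB file.

    Residues whose name is in ``ligand_selector`` become the ligand; waters
    (HOH/WAT/SOL) are dropped; everything else is treated as a protein residue
    and must expose exactly one C-alpha if it is an amino acid.  Coordinates
    are converted from Ångström to nm.  Charges are initialised to zero (the
    PDB format carries none).
    """
    ligand_selector = {str(s).strip().upper() for s in ligand_selector}
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = next(parser.get_structure("duores", str(path)).get_models())
    except PDBConstructionException as exc:
        raise PDBParseError(f"malformed PDB record: {exc}") from exc
    except StopIteration:
        raise PDBParseError(f"{path}: no MODEL/coordinates found") from None

    residues: list[Residue] = []
    ligand: list[Atom] = []
    for chain in model:
        for res in chain:
            resname = res.get_resname().strip().upper()
            if resname in {"HOH", "WAT", "SOL"}:
                continue
            atoms = []
            calpha_index = None
            for i, at in enumerate(res.get_atoms()):
                element = (at.element or "").strip().upper()
                mass = at.mass
                if mass is None or not np.isfinite(mass) or mass <= 0:
                    mass = _element_mass(element, at.get_name())
                atoms.append(
                    Atom(
                        name=at.get_name(),
                        element=element or at.get_name()[:1].upper(),
                        mass=float(mass),
                        charge=0.0,
                        position=np.asarray(at.coord, dtype=float) / ANGSTROM_PER_NM,
                    )
                )
                if at.get_name() == "CA" and element != "CA":  # C-alpha, not calcium ion
                    calpha_index = i
            if resname in ligand_selector:
                ligand.extend(atoms)
                continue
            if calpha_index is None and is_aa(res, standard=False):
                raise StructureError(
                    f"amino-acid residue {resname} {res.id[1]} lacks a CA atom"
                )
            residues.append(
                Residue(
                    index=len(residues) + 1,
                    name=resname,
                    atoms=atoms,
                    calpha_index=calpha_index,
                )
            )

    if not residues:
        raise StructureError(f"{path}: no protein residues found")
    coords = np.concatenate(
        [r.positions() for r in residues]
        + ([np.array([a.position for a in ligand])] if ligand else [])
    )
    box = coords.max(axis=0) - coords.min(axis=0) + 1.0
    return Structure(residues=residues, ligand=ligand, box=box)


def _pdb_line(record, serial, name, resname, chain, resseq, pos_nm, element):
    x, y, z = np.asarray(pos_nm) * ANGSTROM_PER_NM
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{record:<6s}{serial:>5d} {name_field} {resname:<3s} {chain}{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def write_pdb(structure: Structure, path, ligand_resname: str = "LIG") -> None:
    """Write a structure as a PDB file (nm converted back to Ångström)."""
    serial = 0
    with open(path, "w") as fh:
        for res in structure.residues:
            for atom in res.atoms:
                serial += 1
                fh.write(
                    _pdb_line("ATOM", serial, atom.name, res.name[:3], "A",
                              res.index, atom.position, atom.element[:2])
                )
        fh.write(f"TER   {serial + 1:>5d}\n")
        lig_resseq = len(structure.residues) + 1
        for atom in structure.ligand:
            serial += 1
            fh.write(
                _pdb_line("HETATM", serial, atom.name, ligand_resname, "A",
                          lig_resseq, atom.position, atom.element[:2])
            )
        fh.write("END\n")


def residue_geometry(residue: Residue) -> tuple[np.ndarray, float]:
    """Mass-weighted centre of mass (nm) and radius of gyration (nm).

    R_g = sqrt( sum_i m_i |r_i - com|^2 / sum_i m_i ), over all atoms.
    """
    if not residue.atoms:
        raise StructureError(f"residue {residue.index} has no atoms")
    masses = residue.masses()
    total = masses.sum()
    if total <= 0:
        raise StructureError(f"residue {residue.index}: zero total mass")
    pos = residue.positions()
    com = masses @ pos / total
    rg = float(np.sqrt((masses * ((pos - com) ** 2).sum(axis=1)).sum() / total))
    return com, rg


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

_SATELLITE_ELEMENTS = ["C", "C", "N", "O", "H"]


def make_toy_complex(n_residues: int, seed: int, pocket_residue: int | None = None
                     ) -> Structure:
    """Generate a deterministic synthetic protein–ligand complex.

    The C-alpha trace follows an ideal alpha-helix (rise 0.15 nm, twist 100
    degrees, radius 0.23 nm, giving a consecutive spacing of ~0.383 nm) with a
    small seeded radial jitter, so consecutive spacings stay within 10% of the
    canonical 0.38 nm.  Each residue carries 3–8 satellite atoms around its
    C-alpha and the ligand (5–20 atoms) sits within 0.5 nm of a designated
    pocket residue, on the outside of the helix.
    """
    if n_residues < 3:
        raise ValueError("a toy complex needs at least 3 residues")
    rng = np.random.default_rng(seed)
    if pocket_residue is None:
        pocket_residue = n_residues // 2 + 1

    rise, twist, radius = 0.15, np.deg2rad(100.0), 0.23
    theta = twist * np.arange(n_residues)
    jitter = rng.uniform(-0.004, 0.004, size=n_residues)
    ca = np.column_stack([
        (radius + jitter) * np.cos(theta),
        (radius + jitter) * np.sin(theta),
        rise * np.arange(n_residues),
    ])

    residues = []
    for i in range(n_residues):
        atoms = [Atom("CA", "C", 12.011, 0.0, ca[i])]
        n_sat = int(rng.integers(3, 9))
        for j in range(n_sat):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng.uniform(0.08, 0.18)
            element = _SATELLITE_ELEMENTS[int(rng.integers(len(_SATELLITE_ELEMENTS)))]
            atoms.append(
                Atom(f"{element}{j + 1}", element, _ELEMENT_MASSES[element], 0.0,
                     ca[i] + dist * direction)
            )
        residues.append(Residue(index=i + 1, name="TOY", atoms=atoms, calpha_index=0))

    # ligand: a compact cluster just outside the helix wall, near the pocket CA
    pocket_ca = ca[pocket_residue - 1]
    outward = pocket_ca - np.array([0.0, 0.0, pocket_ca[2]])
    outward /= np.linalg.norm(outward)
    center = pocket_ca + 0.32 * outward
    n_lig = int(rng.integers(5, 21))
    ligand = []
    for j in range(n_lig):
        offset = rng.normal(scale=0.08, size=3)
        offset = np.clip(offset, -0.15, 0.15)
        element = _SATELLITE_ELEMENTS[int(rng.integers(len(_SATELLITE_ELEMENTS)))]
        ligand.append(
            Atom(f"{element}{j + 1}", element, _ELEMENT_MASSES[element], 0.0,
                 center + offset)
        )

    coords = np.concatenate([ca, [a.position for a in ligand]])
    box = coords.max(axis=0) - coords.min(axis=0) + 2.0
    return Structure(residues=residues, ligand=ligand, box=box)
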