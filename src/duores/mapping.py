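"""Resolution mapping: which residues stay atomistic, which become ENM beads.

The atomistic subset is chosen by ranking residues by the distance between
their centre of mass and the closest ligand atom, and keeping the first
``n_at``.  Residues in direct contact with the ligand (heavy-atom minimum
distance below a cutoff) are expected to occupy the head of that ranking; the
selection asserts this whenever ``n_at`` is large enough to cover them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import MappingError
from .structures import Structure, residue_geometry

__all__ = [
    "Mapping",
    "contact_residues",
    "rank_by_ligand_distance",
    "select_atomistic",
    "write_mapping",
    "read_mapping",
]

#: default heavy-atom contact cutoff, nm
DEFAULT_CONTACT_CUTOFF = 0.45


@dataclass
class Mapping:
    """Partition of residues into atomistic and coarse-grained sets.

    ``atomistic`` is ordered by increasing centre-of-mass distance to the
    ligand; ``cg`` is ordered by residue index.  ``rank_distance`` maps every
    residue index to its ranking distance (nm).
    """

    atomistic: list[int]
    cg: list[int]
    rank_distance: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        at, cg = set(self.atomistic), set(self.cg)
        if at & cg:
            raise MappingError(f"residues in both sets: {sorted(at & cg)}")
        if len(at) != len(self.atomistic) or len(cg) != len(self.cg):
            raise MappingError("duplicate residue indices in mapping")

    @property
    def n_at(self) -> int:
        return len(self.atomistic)

    @property
    def all_residues(self) -> list[int]:
        return sorted(set(self.atomistic) | set(self.cg))


def _heavy_positions(atoms) -> np.ndarray:
    pos = [a.position for a in atoms if a.element.upper() != "H"]
    return np.array(pos) if pos else np.empty((0, 3))


def contact_residues(structure: Structure, cutoff: float = DEFAULT_CONTACT_CUTOFF
                     ) -> set[int]:
    """Residues whose minimum heavy-atom distance to the ligand is <= cutoff."""
    structure.require_ligand()
    lig = _heavy_positions(structure.ligand)
    contacts = set()
    for res in structure.residues:
        pos = _heavy_positions(res.atoms)
        if len(pos) == 0 or len(lig) == 0:
            continue
        if cdist(pos, lig).min() <= cutoff:
            contacts.add(res.index)
    return contacts


def rank_by_ligand_distance(structure: Structure) -> list[tuple[int, float]]:
    """Residues sorted by centre-of-mass distance to the closest ligand atom.

    Ties are broken by ascending residue index.
    """
    lig = structure.ligand_positions()
    entries = []
    for res in structure.residues:
        com, _ = residue_geometry(res)
        d = float(np.linalg.norm(lig - com, axis=1).min())
        entries.append((res.index, d))
    return sorted(entries, key=lambda e: (e[1], e[0]))


def select_atomistic(structure: Structure, n_at: int,
                     contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> Mapping:
    """Keep the ``n_at`` residues closest to the ligand atomistic.

    When ``n_at`` is at least the number of direct-contact residues, the
    atomistic set must contain all of them; a violation indicates a geometry
    where centre-of-mass ranking and atom-level contacts disagree, and is
    reported as an error rather than silently accepted.
    """
    n_res = structure.n_residues
    if not 0 <= n_at <= n_res:
        raise ValueError(f"n_at={n_at} outside [0, {n_res}]")
    ranking = rank_by_ligand_distance(structure)
    atomistic = [idx for idx, _ in ranking[:n_at]]
    cg = sorted(idx for idx, _ in ranking[n_at:])
    contacts = contact_residues(structure, contact_cutoff)
    if n_at >= len(contacts) and not contacts <= set(atomistic):
        missing = sorted(contacts - set(atomistic))
        raise MappingError(
            f"contact residues {missing} not covered by the {n_at} closest; "
            "centre-of-mass ranking disagrees with atom-level contacts"
        )
    return Mapping(atomistic=atomistic, cg=cg, rank_distance=dict(ranking))


def write_mapping(mapping: Mapping, path) -> None:
    """Serialize as a two-column table: residue index, AT|CG."""
    with open(path, "w") as fh:
        fh.write("# residue  resolution\n")
        at = set(mapping.atomistic)
        for idx in mapping.all_residues:
            fh.write(f"{idx:6d}  {'AT' if idx in at else 'CG'}\n")


def read_mapping(path) -> Mapping:
    atomistic, cg = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx_s, tag = line.split()
            (atomistic if tag.upper() == "AT" else cg).append(int(idx_s))
    return Mapping(atomistic=atomistic, cg=sorted(cg))
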