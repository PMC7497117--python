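"""C-alpha elastic network: topology, energy, Hessian, RMSF, spring fitting.

The network places one bead on the C-alpha of every coarse-grained residue
and penalizes deviations of inter-bead distances from their values in the
reference (native) conformation:

    E = sum_{i<j} k_ij (r_ij - r_ij0)^2 * theta(r_c - r_ij0)

Two spring species are used: a stiff backbone constant ``k_b`` between beads
of consecutive residues (bonded regardless of separation) and a weaker
``k_nb`` between all other bead pairs whose native distance lies below the
cutoff ``r_c``.  Note the energy carries no 1/2 prefactor, so the effective
harmonic stiffness of a bond is ``2 k``; all defaults are quoted in this
convention.

Equilibrium fluctuations follow from the Hessian at the native state: the
covariance is ``k_B T`` times the pseudo-inverse of the Hessian with the
rigid-body null space removed, and the per-bead RMSF is the square root of
the trace of its 3x3 diagonal block.  Bead masses never enter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE
from .errors import IllConditionedNetworkError, StructureError
from .mapping import Mapping
from .structures import Structure

__all__ = [
    "ENMParams",
    "ENMTopology",
    "build_enm",
    "enm_energy",
    "enm_forces",
    "enm_hessian",
    "rmsf_from_hessian",
    "fit_knb",
    "write_rmsf_profile",
    "read_rmsf_profile",
]

#: relative eigenvalue threshold below which a mode counts as rigid-body
ZERO_MODE_RTOL = 1e-8


@dataclass
class ENMParams:
    """Spring constants (kJ mol^-1 nm^-2) and native-distance cutoff (nm)."""

    k_b: float = 5.0e4
    k_nb: float = 160.0
    r_c: float = 1.2

    def __post_init__(self):
        if self.k_b <= 0:
            raise ValueError(f"k_b must be positive, got {self.k_b}")
        if self.k_nb < 0:
            raise ValueError(f"k_nb must be non-negative, got {self.k_nb}")
        if self.r_c <= 0:
            raise ValueError(f"r_c must be positive, got {self.r_c}")


@dataclass
class ENMTopology:
    """Bead reference positions (N x 3, nm) and harmonic bonds.

    Bonds are stored as parallel arrays ``(i, j, k, r0)`` with ``i < j`` and
    no duplicate pairs.  ``bead_residues`` records which residue each bead
    came from (1-based), for bookkeeping and serialization.
    """

    bead_positions: np.ndarray
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    bead_residues: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.bead_positions = np.asarray(self.bead_positions, dtype=float)
        self.bond_i = np.asarray(self.bond_i, dtype=int)
        self.bond_j = np.asarray(self.bond_j, dtype=int)
        self.bond_k = np.asarray(self.bond_k, dtype=float)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        if np.any(self.bond_i >= self.bond_j):
            raise ValueError("bonds must satisfy i < j")
        pairs = set(zip(self.bond_i.tolist(), self.bond_j.tolist()))
        if len(pairs) != len(self.bond_i):
            raise ValueError("duplicate bond pairs")

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_i)

    def bonds(self):
        """Iterate bonds as (i, j, k, r0) tuples."""
        yield from zip(self.bond_i, self.bond_j, self.bond_k, self.bond_r0)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "i": self.bond_i, "j": self.bond_j,
            "k": self.bond_k, "r0": self.bond_r0,
        }).to_csv(path, index=False)


def build_enm(structure: Structure, mapping: Mapping, params: ENMParams | None = None
              ) -> ENMTopology:
    """Build the elastic network over the coarse-grained beads of a mapping.

    Beads of consecutive residues (indices differing by one) are connected
    with the stiff backbone spring whatever their distance; any other bead
    pair is connected with the weak spring iff its native distance is below
    the cutoff.  Native distances come from the reference conformation.
    """
    params = params or ENMParams()
    residues = sorted(mapping.cg)
    for idx in residues:
        if structure.residues[idx - 1].calpha_index is None:
            raise StructureError(f"coarse-grained residue {idx} lacks a C-alpha")
    pos = structure.calpha_positions(residues)
    n = len(residues)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)

    bi, bj, bk, br0 = [], [], [], []
    for a in range(n):
        for b in range(a + 1, n):
            backbone = residues[b] - residues[a] == 1
            if backbone:
                k = params.k_b
            elif dist[a, b] < params.r_c:
                k = params.k_nb
            else:
                continue
            bi.append(a)
            bj.append(b)
            bk.append(k)
            br0.append(dist[a, b])
    return ENMTopology(pos, np.array(bi), np.array(bj), np.array(bk),
                       np.array(br0), bead_residues=list(residues))


def _check_positions(topology: ENMTopology, positions) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if positions.shape != topology.bead_positions.shape:
        raise ValueError(
            f"positions shape {positions.shape} does not match topology "
            f"({topology.bead_positions.shape})"
        )
    return positions


def enm_energy(topology: ENMTopology, positions) -> float:
    """Network energy sum_bonds k (r - r0)^2, kJ/mol."""
    positions = _check_positions(topology, positions)
    d = positions[topology.bond_j] - positions[topology.bond_i]
    r = np.linalg.norm(d, axis=1)
    return float(np.sum(topology.bond_k * (r - topology.bond_r0) ** 2))


def enm_forces(topology: ENMTopology, positions) -> np.ndarray:
    """Forces -dE/dr on every bead, kJ mol^-1 nm^-1."""
    positions = _check_positions(topology, positions)
    d = positions[topology.bond_j] - positions[topology.bond_i]
    r = np.linalg.norm(d, axis=1)
    # dE/d(r_j) = 2 k (r - r0) * d/r
    coeff = 2.0 * topology.bond_k * (r - topology.bond_r0) / r
    pair_force = coeff[:, None] * d
    forces = np.zeros_like(positions)
    np.add.at(forces, topology.bond_j, -pair_force)
    np.add.at(forces, topology.bond_i, pair_force)
    return forces


def enm_hessian(topology: ENMTopology) -> np.ndarray:
    """Analytic 3N x 3N Hessian at the native state, kJ mol^-1 nm^-2.

    At the reference conformation every bond length equals its native value,
    so each bond contributes ``2 k (u u^T)`` along its unit vector ``u``; the
    transverse curvature vanishes there.
    """
    n = topology.n_beads
    if n < 2:
        raise ValueError("a network needs at least two beads")
    h = np.zeros((3 * n, 3 * n))
    d = topology.bead_positions[topology.bond_j] - topology.bead_positions[topology.bond_i]
    r = np.linalg.norm(d, axis=1)
    u = d / r[:, None]
    for idx in range(topology.n_bonds):
        i, j = topology.bond_i[idx], topology.bond_j[idx]
        block = 2.0 * topology.bond_k[idx] * np.outer(u[idx], u[idx])
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[si, si] += block
        h[sj, sj] += block
        h[si, sj] -= block
        h[sj, si] -= block
    return h


def rmsf_from_hessian(hessian: np.ndarray, temperature: float = DEFAULT_TEMPERATURE,
                      max_rigid_modes: int = 6) -> np.ndarray:
    """Per-bead RMSF (nm) from the thermal covariance of a harmonic network.

    The covariance is ``k_B T H^+`` where the pseudo-inverse excludes modes
    with eigenvalue below ``1e-8`` times the largest one.  More than six such
    modes means the network has internal soft directions (disconnected or
    collinear) and the harmonic fluctuation problem is ill-posed.
    """
    hessian = np.asarray(hessian, dtype=float)
    evals, evecs = np.linalg.eigh(hessian)
    tol = ZERO_MODE_RTOL * evals.max()
    soft = evals < tol
    if soft.sum() > max_rigid_modes:
        raise IllConditionedNetworkError(
            f"{int(soft.sum())} near-zero modes, more than the "
            f"{max_rigid_modes} rigid-body motions: network is ill-conditioned"
        )
    inv = np.where(soft, 0.0, 1.0 / np.where(soft, 1.0, evals))
    kt = KB * temperature
    # diagonal of the covariance: sum_m v_im^2 * kT / eval_m
    var = kt * (evecs ** 2) @ inv
    return np.sqrt(var.reshape(-1, 3).sum(axis=1))


def _golden_section(fun, lo, hi, rtol):
    """Golden-section minimization on [lo, hi]; returns the abscissa."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while abs(b - a) > rtol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


def fit_knb(structure: Structure, mapping: Mapping, reference_rmsf,
            params: ENMParams | None = None,
            temperature: float = DEFAULT_TEMPERATURE,
            bounds: tuple[float, float] = (1e-1, 1e6),
            rtol: float = 1e-3) -> float:
    """Fit the non-bonded spring constant to a reference RMSF profile.

    Minimizes the root-mean-square error between the network's predicted
    C-alpha RMSF and ``reference_rmsf`` over ``k_nb``, holding ``k_b`` and the
    cutoff fixed, with a golden-section search on log k_nb.  Because only the
    spring magnitudes change, the Hessian is assembled once as a backbone part
    plus a unit-strength non-bonded part and rescaled per evaluation.
    """
    params = params or ENMParams()
    reference_rmsf = np.asarray(reference_rmsf, dtype=float)
    if np.any(reference_rmsf <= 0) or not np.all(np.isfinite(reference_rmsf)):
        raise ValueError("reference RMSF values must be positive and finite")

    topo = build_enm(structure, mapping, ENMParams(params.k_b, 1.0, params.r_c))
    if len(reference_rmsf) != topo.n_beads:
        raise ValueError(
            f"reference profile has {len(reference_rmsf)} entries for "
            f"{topo.n_beads} beads"
        )
    backbone = np.isclose(topo.bond_k, params.k_b)
    kb_topo = ENMTopology(topo.bead_positions, topo.bond_i[backbone],
                          topo.bond_j[backbone], topo.bond_k[backbone],
                          topo.bond_r0[backbone])
    nb = ~backbone
    h_b = enm_hessian(kb_topo)
    if nb.sum() == 0:
        raise ValueError("network has no non-bonded springs to fit")
    nb_topo = ENMTopology(topo.bead_positions, topo.bond_i[nb], topo.bond_j[nb],
                          np.ones(int(nb.sum())), topo.bond_r0[nb])
    h_nb_unit = enm_hessian(nb_topo)

    def rmse_log(log_k):
        rmsf = rmsf_from_hessian(h_b + np.exp(log_k) * h_nb_unit, temperature)
        return float(np.sqrt(np.mean((rmsf - reference_rmsf) ** 2)))

    log_opt = _golden_section(rmse_log, np.log(bounds[0]), np.log(bounds[1]),
                              rtol=rtol)
    return float(np.exp(log_opt))


def write_rmsf_profile(rmsf, path, indices=None) -> None:
    """Two-column plain text: residue index, RMSF in nm."""
    rmsf = np.asarray(rmsf, dtype=float)
    indices = range(1, len(rmsf) + 1) if indices is None else indices
    with open(path, "w") as fh:
        fh.write("# residue  rmsf_nm\n")
        for idx, value in zip(indices, rmsf):
            fh.write(f"{idx:6d}  {value:.6f}\n")


def read_rmsf_profile(path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.append(float(line.split()[1]))
    return np.array(values)
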