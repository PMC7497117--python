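"""Lambda-dependent potentials for alchemical transformations.

Covers the pair potentials (Lennard-Jones, reaction-field Coulomb), the
Beutler-style soft-core Lennard-Jones used to keep endpoint states finite,
the Boresch orientational restraint energy (one distance, two angles, three
dihedrals), and a composite lambda-Hamiltonian whose analytic
lambda-derivative feeds thermodynamic integration.

Alchemical staging on the complex leg is restraints on -> Coulomb off ->
Lennard-Jones off; on the ligand leg Coulomb on <- Lennard-Jones on.  Charges
are scaled linearly in lambda (no Coulomb soft core is needed while the
Lennard-Jones cores are intact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import F_COULOMB
from .errors import GeometryError

__all__ = [
    "SoftCoreParams",
    "ElectrostaticsParams",
    "BoreschRestraints",
    "AlchemicalTerm",
    "LambdaHamiltonian",
    "lj_energy",
    "lj_force",
    "coulomb_rf_energy",
    "coulomb_rf_force",
    "softcore_lj",
    "softcore_lj_force",
    "boresch_energy",
    "boresch_forces",
    "measure_boresch",
    "du_dlambda",
    "read_restraints",
    "write_restraints",
]


@dataclass
class SoftCoreParams:
    """Soft-core shape parameters alpha and power p."""

    alpha: float = 0.5
    p: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.p <= 0:
            raise ValueError(f"p must be > 0, got {self.p}")


@dataclass
class ElectrostaticsParams:
    """Reaction-field electrostatics: dielectric and cutoff (nm)."""

    eps_rf: float = 80.0
    r_cut: float = 1.2

    def __post_init__(self):
        if self.eps_rf < 1:
            raise ValueError(f"eps_rf must be >= 1, got {self.eps_rf}")
        if self.r_cut <= 0:
            raise ValueError(f"r_cut must be positive, got {self.r_cut}")

    @property
    def k_rf(self) -> float:
        """(eps_rf - 1) / ((2 eps_rf + 1) r_cut^3), nm^-3."""
        return (self.eps_rf - 1.0) / ((2.0 * self.eps_rf + 1.0) * self.r_cut ** 3)

    @property
    def c_rf(self) -> float:
        """Shift constant 1/r_cut + k_rf r_cut^2 making U vanish at the cutoff."""
        return 1.0 / self.r_cut + self.k_rf * self.r_cut ** 2


def lj_energy(r, sigma, epsilon, r_cut: float | None = None):
    """Plain Lennard-Jones 4 eps [(s/r)^12 - (s/r)^6], truncated at r_cut."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Lennard-Jones energy requires r > 0")
    sr6 = (np.asarray(sigma, dtype=float) / r) ** 6
    u = 4.0 * np.asarray(epsilon, dtype=float) * (sr6 ** 2 - sr6)
    if r_cut is not None:
        u = np.where(r <= r_cut, u, 0.0)
    return u if u.ndim else float(u)


def coulomb_rf_energy(r, q_i, q_j, params: ElectrostaticsParams | None = None):
    """Reaction-field Coulomb energy, kJ/mol.

    U = f q_i q_j (1/r + k_rf r^2 - c_rf) for r <= r_cut, zero beyond; the
    shift makes the energy continuous (zero) at the cutoff.
    """
    params = params or ElectrostaticsParams()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Coulomb energy requires r > 0")
    qq = np.asarray(q_i, dtype=float) * np.asarray(q_j, dtype=float)
    u = np.where(r <= params.r_cut,
                 F_COULOMB * qq * (1.0 / r + params.k_rf * r ** 2 - params.c_rf),
                 0.0)
    return u if u.ndim else float(u)


def softcore_lj(r, sigma, epsilon, lambda_coupling, sc: SoftCoreParams | None = None):
    """Soft-core Lennard-Jones and its analytic lambda-derivative.

    U = lam * 4 eps [ (s^6/A)^2 - s^6/A ],  A = alpha s^6 (1-lam)^p + r^6.

    Finite at r = 0 whenever lam < 1; reduces exactly to plain Lennard-Jones
    at lam = 1 and to zero at lam = 0.  Returns ``(U, dU/dlam)``.
    """
    sc = sc or SoftCoreParams()
    lam = float(lambda_coupling)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    if lam == 1.0 and np.any(r == 0) and sc.alpha * (1 - lam) ** sc.p == 0:
        raise ValueError("r = 0 is singular at lambda = 1")
    sigma6 = np.asarray(sigma, dtype=float) ** 6
    eps = np.asarray(epsilon, dtype=float)
    a = sc.alpha * sigma6 * (1.0 - lam) ** sc.p + r ** 6
    b = sigma6 / a
    u = lam * 4.0 * eps * (b ** 2 - b)
    # dB/dlam = B * alpha s^6 p (1-lam)^(p-1) / A
    db = b * sc.alpha * sigma6 * sc.p * (1.0 - lam) ** (sc.p - 1.0) / a
    dudl = 4.0 * eps * (b ** 2 - b) + lam * 4.0 * eps * (2.0 * b - 1.0) * db
    if u.ndim:
        return u, dudl
    return float(u), float(dudl)


def lj_force(r, sigma, epsilon, r_cut: float | None = None):
    """Radial Lennard-Jones force -dU/dr, kJ mol^-1 nm^-1."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Lennard-Jones force requires r > 0")
    sr6 = (np.asarray(sigma, dtype=float) / r) ** 6
    f = 24.0 * np.asarray(epsilon, dtype=float) * (2.0 * sr6 ** 2 - sr6) / r
    if r_cut is not None:
        f = np.where(r <= r_cut, f, 0.0)
    return f if f.ndim else float(f)


def coulomb_rf_force(r, q_i, q_j, params: ElectrostaticsParams | None = None):
    """Radial reaction-field force -dU/dr = f q_i q_j (1/r^2 - 2 k_rf r)."""
    params = params or ElectrostaticsParams()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Coulomb force requires r > 0")
    qq = np.asarray(q_i, dtype=float) * np.asarray(q_j, dtype=float)
    f = np.where(r <= params.r_cut,
                 F_COULOMB * qq * (1.0 / r ** 2 - 2.0 * params.k_rf * r), 0.0)
    return f if f.ndim else float(f)


def softcore_lj_force(r, sigma, epsilon, lambda_coupling,
                      sc: SoftCoreParams | None = None):
    """Radial soft-core force -dU/dr at fixed lambda."""
    sc = sc or SoftCoreParams()
    lam = float(lambda_coupling)
    r = np.asarray(r, dtype=float)
    sigma6 = np.asarray(sigma, dtype=float) ** 6
    eps = np.asarray(epsilon, dtype=float)
    a = sc.alpha * sigma6 * (1.0 - lam) ** sc.p + r ** 6
    b = sigma6 / a
    # dU/dr = lam 4 eps (2B - 1) dB/dr,  dB/dr = -6 r^5 sigma^6 / A^2
    f = lam * 24.0 * eps * (2.0 * b - 1.0) * b * r ** 5 / a
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# Boresch restraints
# ---------------------------------------------------------------------------

def _angle(p0, p1, p2) -> float:
    """Angle at vertex p1, radians."""
    v0, v2 = p0 - p1, p2 - p1
    n0, n2 = np.linalg.norm(v0), np.linalg.norm(v2)
    if n0 == 0 or n2 == 0:
        raise GeometryError("coincident atoms in angle")
    cosang = np.clip(v0 @ v2 / (n0 * n2), -1.0, 1.0)
    return float(np.arccos(cosang))


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral, radians in (-pi, pi]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("collinear anchor triple: dihedral undefined")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.arctan2(m1 @ n2, n1 @ n2))


def wrap_angle(delta) -> np.ndarray | float:
    """Smallest signed angular difference, wrapped to (-pi, pi]."""
    wrapped = -((-np.asarray(delta) + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass
class BoreschRestraints:
    """One distance, two angles, three dihedrals tying ligand to protein.

    ``protein_anchors`` = (P1, P2, P3) and ``ligand_anchors`` = (L1, L2, L3)
    index into a configuration array; P1 and L1 are the atoms joined by the
    distance restraint.  Internal coordinates: r = |P1 L1|;
    thetaA = P2-P1-L1, thetaB = P1-L1-L2; phiA = P3-P2-P1-L1,
    phiB = P2-P1-L1-L2, phiC = P1-L1-L2-L3.  Force constants in
    kJ mol^-1 nm^-2 (distance) and kJ mol^-1 rad^-2 (angles, dihedrals).
    """

    protein_anchors: tuple[int, int, int]
    ligand_anchors: tuple[int, int, int]
    r0: float
    theta_a0: float
    theta_b0: float
    phi_a0: float
    phi_b0: float
    phi_c0: float
    k_r: float
    k_theta_a: float
    k_theta_b: float
    k_phi_a: float
    k_phi_b: float
    k_phi_c: float

    def __post_init__(self):
        anchors = tuple(self.protein_anchors) + tuple(self.ligand_anchors)
        if len(set(anchors)) != 6:
            raise ValueError("the six restraint anchors must be distinct atoms")
        for name in ("k_r", "k_theta_a", "k_theta_b", "k_phi_a", "k_phi_b", "k_phi_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("theta_a0", "theta_b0"):
            if not 0.0 < getattr(self, name) < np.pi:
                raise ValueError(f"{name} must lie strictly inside (0, pi)")

    @property
    def force_constants(self) -> np.ndarray:
        return np.array([self.k_r, self.k_theta_a, self.k_theta_b,
                         self.k_phi_a, self.k_phi_b, self.k_phi_c])

    @classmethod
    def from_configuration(cls, coords, protein_anchors, ligand_anchors,
                           k_r: float = 4184.0, k_angle: float = 41.84,
                           k_dihedral: float = 41.84) -> "BoreschRestraints":
        """Build restraints whose reference values match a given pose."""
        coords = np.asarray(coords, dtype=float)
        p1, p2, p3 = (coords[i] for i in protein_anchors)
        l1, l2, l3 = (coords[i] for i in ligand_anchors)
        return cls(
            protein_anchors=tuple(protein_anchors),
            ligand_anchors=tuple(ligand_anchors),
            r0=float(np.linalg.norm(p1 - l1)),
            theta_a0=_angle(p2, p1, l1),
            theta_b0=_angle(p1, l1, l2),
            phi_a0=_dihedral(p3, p2, p1, l1),
            phi_b0=_dihedral(p2, p1, l1, l2),
            phi_c0=_dihedral(p1, l1, l2, l3),
            k_r=k_r, k_theta_a=k_angle, k_theta_b=k_angle,
            k_phi_a=k_dihedral, k_phi_b=k_dihedral, k_phi_c=k_dihedral,
        )


def measure_boresch(coords, restraints: BoreschRestraints) -> np.ndarray:
    """The six restrained internal coordinates (r, thetaA, thetaB, phiA..C)."""
    coords = np.asarray(coords, dtype=float)
    p1, p2, p3 = (coords[i] for i in restraints.protein_anchors)
    l1, l2, l3 = (coords[i] for i in restraints.ligand_anchors)
    return np.array([
        np.linalg.norm(p1 - l1),
        _angle(p2, p1, l1),
        _angle(p1, l1, l2),
        _dihedral(p3, p2, p1, l1),
        _dihedral(p2, p1, l1, l2),
        _dihedral(p1, l1, l2, l3),
    ])


def boresch_energy(coords, restraints: BoreschRestraints,
                   lambda_restr: float = 1.0) -> float:
    """Restraint energy lam * sum 1/2 k (x - x0)^2, kJ/mol.

    Dihedral deviations are wrapped to the smallest signed difference.
    """
    if not 0.0 <= lambda_restr <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lambda_restr}")
    if lambda_restr == 0.0:
        return 0.0
    x = measure_boresch(coords, restraints)
    x0 = np.array([restraints.r0, restraints.theta_a0, restraints.theta_b0,
                   restraints.phi_a0, restraints.phi_b0, restraints.phi_c0])
    dx = x - x0
    dx[3:] = wrap_angle(dx[3:])
    return float(lambda_restr * 0.5 * np.sum(restraints.force_constants * dx ** 2))


def _angle_grad(p0, p1, p2):
    """Gradients of the angle at vertex p1 w.r.t. the three points."""
    u, v = p0 - p1, p2 - p1
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cosang = np.clip(uh @ vh, -1.0, 1.0)
    sinang = np.sqrt(max(1.0 - cosang ** 2, 1e-24))
    g0 = (cosang * uh - vh) / (nu * sinang)
    g2 = (cosang * vh - uh) / (nv * sinang)
    return g0, -(g0 + g2), g2


def _dihedral_grad(p0, p1, p2, p3):
    """Gradients of the signed dihedral w.r.t. the four points."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    g0 = nb2 / (n1 @ n1) * n1
    g3 = -nb2 / (n2 @ n2) * n2
    s12 = (b1 @ b2) / (nb2 ** 2)
    s32 = (b3 @ b2) / (nb2 ** 2)
    g1 = -(1.0 + s12) * g0 + s32 * g3
    g2 = -(g0 + g1 + g3)  # translation invariance
    return g0, g1, g2, g3


def boresch_forces(coords, restraints: BoreschRestraints,
                   lambda_restr: float = 1.0) -> np.ndarray:
    """Analytic forces of the restraint energy on every atom, kJ mol^-1 nm^-1."""
    coords = np.asarray(coords, dtype=float)
    forces = np.zeros_like(coords)
    if lambda_restr == 0.0:
        return forces
    ip1, ip2, ip3 = restraints.protein_anchors
    il1, il2, il3 = restraints.ligand_anchors
    p1, p2, p3 = coords[ip1], coords[ip2], coords[ip3]
    l1, l2, l3 = coords[il1], coords[il2], coords[il3]
    x = measure_boresch(coords, restraints)
    x0 = np.array([restraints.r0, restraints.theta_a0, restraints.theta_b0,
                   restraints.phi_a0, restraints.phi_b0, restraints.phi_c0])
    dx = x - x0
    dx[3:] = wrap_angle(dx[3:])
    pref = lambda_restr * restraints.force_constants * dx  # dE/dcoordinate

    # distance P1-L1
    rh = (p1 - l1) / x[0]
    forces[ip1] -= pref[0] * rh
    forces[il1] += pref[0] * rh
    # angle thetaA: P2-P1-L1 (vertex P1)
    for idx, g in zip((ip2, ip1, il1), _angle_grad(p2, p1, l1)):
        forces[idx] -= pref[1] * g
    # angle thetaB: P1-L1-L2 (vertex L1)
    for idx, g in zip((ip1, il1, il2), _angle_grad(p1, l1, l2)):
        forces[idx] -= pref[2] * g
    # dihedrals phiA, phiB, phiC
    for k, quad in zip(
        (3, 4, 5),
        (((ip3, p3), (ip2, p2), (ip1, p1), (il1, l1)),
         ((ip2, p2), (ip1, p1), (il1, l1), (il2, l2)),
         ((ip1, p1), (il1, l1), (il2, l2), (il3, l3))),
    ):
        grads = _dihedral_grad(*(p for _, p in quad))
        for (idx, _), g in zip(quad, grads):
            forces[idx] -= pref[k] * g
    return forces


# ---------------------------------------------------------------------------
# composite lambda Hamiltonian
# ---------------------------------------------------------------------------

@dataclass
class AlchemicalTerm:
    """One named energy term of the mixed Hamiltonian.

    ``energy(x, lam)`` and ``dudl(x, lam)`` evaluate the term and its
    lambda-derivative.  A term whose ``scaled`` flag is off is evaluated at
    lam = 1 (fully on) and contributes nothing to dU/dlambda.
    """

    name: str
    energy: Callable[[np.ndarray, float], float]
    dudl: Callable[[np.ndarray, float], float]
    scaled: bool = True


class LambdaHamiltonian:
    """Mixed Hamiltonian U_lambda with per-term scaling flags.

    For the canonical linear mixing U = lam U_A + (1 - lam) U_B (state B at
    lam = 0, state A at lam = 1) use :meth:`linear_mix`; the derivative is
    then U_A - U_B at every lambda.
    """

    def __init__(self, terms: list[AlchemicalTerm], lam: float = 0.0):
        self.terms = list(terms)
        self.lam = lam

    @property
    def lam(self) -> float:
        return self._lam

    @lam.setter
    def lam(self, value: float):
        value = float(value)
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {value}")
        self._lam = value

    def energy(self, x) -> float:
        return sum(
            t.energy(x, self._lam if t.scaled else 1.0) for t in self.terms
        )

    def du_dlambda(self, x) -> float:
        return sum(t.dudl(x, self._lam) for t in self.terms if t.scaled)

    @classmethod
    def linear_mix(cls, u_a: Callable, u_b: Callable, lam: float = 0.0
                   ) -> "LambdaHamiltonian":
        term = AlchemicalTerm(
            name="linear_mix",
            energy=lambda x, l: l * u_a(x) + (1.0 - l) * u_b(x),
            dudl=lambda x, l: u_a(x) - u_b(x),
        )
        return cls([term], lam=lam)


def du_dlambda(hamiltonian: LambdaHamiltonian, configuration) -> float:
    """Analytic dU/dlambda of the flagged terms at the current lambda."""
    return hamiltonian.du_dlambda(configuration)


# ---------------------------------------------------------------------------
# restraint definition I/O (flat key-value text block)
# ---------------------------------------------------------------------------

_RESTRAINT_KEYS = [
    "r0", "theta_a0", "theta_b0", "phi_a0", "phi_b0", "phi_c0",
    "k_r", "k_theta_a", "k_theta_b", "k_phi_a", "k_phi_b", "k_phi_c",
]


def write_restraints(restraints: BoreschRestraints, path) -> None:
    with open(path, "w") as fh:
        fh.write("# Boresch restraint definition (nm, rad, kJ/mol)\n")
        fh.write("protein_anchors = %d %d %d\n" % tuple(restraints.protein_anchors))
        fh.write("ligand_anchors = %d %d %d\n" % tuple(restraints.ligand_anchors))
        for key in _RESTRAINT_KEYS:
            fh.write(f"{key} = {getattr(restraints, key)!r}\n")


def read_restraints(path) -> BoreschRestraints:
    fields: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key in ("protein_anchors", "ligand_anchors"):
                fields[key] = tuple(int(v) for v in value.split())
            else:
                fields[key] = float(value)
    return BoreschRestraints(**fields)
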