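"""Excluded-volume coupling of coarse-grained beads to their surroundings.

Coarse-grained beads interact with solvent sites (and with the atomistic
region) through a purely repulsive Weeks–Chandler–Andersen potential.  The
per-bead size is tied to the residue's shape: sigma_i = R_g,i * c, with a
single dimensionless scale factor c shared by all residues.  The factor c is
calibrated against a scalar observable (for the original parameterization,
the bulk water density next to the protein) by bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError
from .mapping import Mapping
from .structures import Structure, residue_geometry

__all__ = [
    "CouplingParams",
    "wca_energy",
    "wca_force",
    "assign_sigmas",
    "calibrate_c",
    "write_coupling_table",
]

#: minimum bead radius (nm) for degenerate single-atom residues
SIGMA_FLOOR = 0.05

#: 2^(1/6): the WCA cutoff in units of sigma
WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass
class CouplingParams:
    """WCA well depth (kJ/mol), scale factor c, and per-bead sigmas (nm)."""

    epsilon: float = 0.34
    c: float = 0.658
    sigma: np.ndarray | None = None

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("all sigmas must be positive")


def wca_energy(r, sigma, epsilon: float = 0.34):
    """Purely repulsive WCA energy, kJ/mol.

    U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps  for r < 2^(1/6) sigma,
    and zero beyond; continuous and non-negative everywhere.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("WCA energy requires r > 0")
    sigma = np.asarray(sigma, dtype=float)
    sr6 = (sigma / r) ** 6
    u = np.where(r < WCA_CUTOFF_FACTOR * sigma,
                 4.0 * epsilon * (sr6 ** 2 - sr6) + epsilon, 0.0)
    return u if u.ndim else float(u)


def wca_force(r, sigma, epsilon: float = 0.34):
    """Radial force -dU/dr (>= 0: purely repulsive), kJ mol^-1 nm^-1."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("WCA force requires r > 0")
    sigma = np.asarray(sigma, dtype=float)
    sr6 = (sigma / r) ** 6
    f = np.where(r < WCA_CUTOFF_FACTOR * sigma,
                 24.0 * epsilon * (2.0 * sr6 ** 2 - sr6) / r, 0.0)
    return f if f.ndim else float(f)


def assign_sigmas(structure: Structure, mapping: Mapping, c: float = 0.658,
                  epsilon: float = 0.34) -> CouplingParams:
    """Derive per-bead WCA sigmas from residue radii of gyration.

    sigma_i = R_g,i * c for every coarse-grained residue, in bead order
    (ascending residue index).  Single-atom residues have R_g = 0; their
    sigma is floored at 0.05 nm with a warning.
    """
    params = CouplingParams(epsilon=epsilon, c=c)  # validates c, epsilon
    sigmas = []
    for idx in sorted(mapping.cg):
        _, rg = residue_geometry(structure.residues[idx - 1])
        sigma = rg * c
        if sigma < SIGMA_FLOOR:
            warnings.warn(
                f"residue {idx}: sigma {sigma:.4f} nm below floor, "
                f"using {SIGMA_FLOOR} nm", stacklevel=2,
            )
            sigma = SIGMA_FLOOR
        sigmas.append(sigma)
    params.sigma = np.array(sigmas)
    return params


def calibrate_c(objective, target: float, bracket: tuple[float, float],
                tol: float = 1e-4, max_iter: int = 200) -> float:
    """Find c with objective(c) = target by bisection.

    ``objective`` must be monotone over the bracket and straddle the target
    at its endpoints.  Convergence is declared when
    ``|objective(c) - target| <= tol * max(1, |target|)``.  The search is
    deterministic; a stochastic objective should fix its own random seed so
    repeated evaluations at the same c agree.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, f_hi = objective(lo) - target, objective(hi) - target
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise CalibrationError(
            f"objective does not straddle target {target} on [{lo}, {hi}] "
            f"(endpoint residuals {f_lo:.4g}, {f_hi:.4g})"
        )
    atol = tol * max(1.0, abs(target))
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = objective(mid) - target
        if abs(f_mid) <= atol or (hi - lo) < 1e-15 * max(1.0, abs(hi)):
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    raise CalibrationError(f"no convergence within {max_iter} bisections")


def write_coupling_table(params: CouplingParams, path, bead_residues=None) -> None:
    """CSV table (bead index or residue, sigma, epsilon)."""
    import pandas as pd

    sigma = params.sigma if params.sigma is not None else np.array([])
    beads = bead_residues if bead_residues is not None else list(range(len(sigma)))
    pd.DataFrame({
        "bead": beads, "sigma_nm": sigma,
        "epsilon_kj_mol": [params.epsilon] * len(sigma),
    }).to_csv(path, index=False)
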