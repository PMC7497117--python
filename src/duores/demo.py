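"""Self-contained alchemical demo systems.

Two families of systems are provided:

* A one-dimensional *harmonic alchemy* (spring constant morphed from
  ``k_initial`` to ``k_final`` under linear mixing) whose free-energy
  difference has the closed form (kT/2) ln(k_final/k_initial).  All lambda
  windows are propagated side by side in a single vectorized Langevin run, so
  a full TI sweep costs one trajectory.

* A *toy complex* leg: the synthetic protein-ligand fixtures of
  :mod:`duores.structures` equipped with a minimal native-pose force field --
  intra-ligand harmonic bonds, Go-style Lennard-Jones contacts between ligand
  and atomistic residues (per-pair sigma chosen so the native distance sits
  at the potential minimum), reaction-field Coulomb on small synthetic
  charges, WCA repulsion against coarse-grained beads, and Boresch
  restraints.  The receptor is held rigid; only ligand atoms move.  This is
  an illustrative stand-in for a solvated force-field system: it exercises
  every piece of the alchemical machinery at desk scale but carries no
  chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .coupling import CouplingParams, assign_sigmas, wca_energy, wca_force
from .energetics import (
    BoreschRestraints,
    ElectrostaticsParams,
    SoftCoreParams,
    boresch_energy,
    boresch_forces,
    coulomb_rf_energy,
    coulomb_rf_force,
    softcore_lj,
    softcore_lj_force,
)
from .enm import ENMParams, build_enm
from .free_energy import TIResult, boresch_analytic, ti_integrate
from .mapping import Mapping
from .simulate import SimulationParams, System, langevin_run
from .structures import Structure

__all__ = [
    "analytic_harmonic_dg",
    "run_harmonic_alchemy",
    "ToyComplexModel",
    "run_toy_leg",
    "run_toy_cycle",
]

LEGS = ("restraints", "coulomb", "lj")


def analytic_harmonic_dg(k_initial: float, k_final: float,
                         temperature: float = 298.0) -> float:
    """Closed-form dG of morphing E = k x^2: (kT/2) ln(k_final/k_initial)."""
    return 0.5 * KB * temperature * np.log(k_final / k_initial)


def run_harmonic_alchemy(k_initial: float = 100.0, k_final: float = 400.0,
                         n_lambdas: int = 21, mass: float = 10.0,
                         params: SimulationParams | None = None) -> TIResult:
    """TI over a linearly mixed 1-D harmonic oscillator ensemble.

    E_lambda = k_lambda x^2 with k_lambda = (1 - lambda) k_initial
    + lambda k_final; dU/dlambda = (k_final - k_initial) x^2.  One oscillator
    per lambda window, all propagated in the same vectorized run.
    """
    params = params or SimulationParams(n_steps=100_000, sample_stride=1)
    lambdas = np.linspace(0.0, 1.0, n_lambdas)
    k = (1.0 - lambdas) * k_initial + lambdas * k_final

    system = System(
        potential=lambda x: float(np.sum(k * x ** 2)),
        forces=lambda x: -2.0 * k * x,
        masses=mass,
        x0=np.zeros(n_lambdas),
    )
    result = langevin_run(
        system, params,
        record=lambda x: (k_final - k_initial) * x ** 2,
        store_trajectory=False,
    )
    series = [result.series[:, i] for i in range(n_lambdas)]
    return ti_integrate(series, lambdas)


# ---------------------------------------------------------------------------
# toy complex legs
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexModel:
    """Precomputed interaction tables for a toy dual-resolution complex."""

    structure: Structure
    mapping: Mapping
    lig_x0: np.ndarray              # native ligand coordinates (n_lig, 3)
    lig_masses: np.ndarray
    lig_charges: np.ndarray
    at_pos: np.ndarray              # atomistic protein atoms (fixed)
    at_charges: np.ndarray
    cg_pos: np.ndarray              # coarse-grained bead positions (fixed)
    cg_sigma: np.ndarray
    # Go-style ligand/protein contacts: (lig index, sigma) vs every AT atom
    go_sigma: np.ndarray            # (n_lig, n_at) pair sigmas
    go_epsilon: float
    bonds_i: np.ndarray             # intra-ligand bonds
    bonds_j: np.ndarray
    bonds_r0: np.ndarray
    k_intra: float
    restraints: BoreschRestraints
    anchor_pos: np.ndarray          # protein anchor coordinates (3, 3)
    softcore: SoftCoreParams = field(default_factory=SoftCoreParams)
    electrostatics: ElectrostaticsParams = field(default_factory=ElectrostaticsParams)
    wca_epsilon: float = 0.34

    @classmethod
    def build(cls, structure: Structure, mapping: Mapping,
              coupling: CouplingParams | None = None,
              enm_params: ENMParams | None = None,
              go_epsilon: float = 0.4, k_intra: float = 5.0e3,
              charge_magnitude: float = 0.1) -> "ToyComplexModel":
        structure.require_ligand()
        lig_x0 = structure.ligand_positions()
        n_lig = len(lig_x0)
        if n_lig < 3:
            raise ValueError("the toy leg needs a ligand of at least 3 atoms")
        lig_masses = np.array([a.mass for a in structure.ligand])
        # synthetic alternating partial charges, zero net charge when even
        lig_charges = charge_magnitude * (-1.0) ** np.arange(n_lig)
        at_atoms = [a for idx in mapping.atomistic
                    for a in structure.residues[idx - 1].atoms]
        if not at_atoms:
            raise ValueError("the toy leg needs at least one atomistic residue")
        at_pos = np.array([a.position for a in at_atoms])
        at_charges = charge_magnitude * (-1.0) ** np.arange(len(at_atoms))

        coupling = coupling or assign_sigmas(structure, mapping)
        topo = build_enm(structure, mapping, enm_params or ENMParams())
        cg_pos = topo.bead_positions

        # per-pair Go sigmas: native separation at the potential minimum,
        # capped at 0.3 nm so distant pairs keep ordinary atomic sizes
        native_d = np.linalg.norm(lig_x0[:, None, :] - at_pos[None, :, :], axis=-1)
        go_sigma = np.minimum(native_d * 2.0 ** (-1.0 / 6.0), 0.3)

        # rigid-ish ligand: bond every pair at its native distance
        ii, jj = np.triu_indices(n_lig, k=1)
        bonds_r0 = np.linalg.norm(lig_x0[ii] - lig_x0[jj], axis=1)

        # Boresch anchors: three C-alphas of the closest atomistic residues,
        # and the three most mutually distant ligand atoms
        anchor_res = mapping.atomistic[:3]
        anchor_pos = structure.calpha_positions(anchor_res)
        lig_anchor = _spread_indices(lig_x0)
        coords0 = np.vstack([anchor_pos, lig_x0])
        restraints = BoreschRestraints.from_configuration(
            coords0, protein_anchors=(0, 1, 2),
            ligand_anchors=tuple(3 + i for i in lig_anchor),
        )
        return cls(
            structure=structure, mapping=mapping, lig_x0=lig_x0,
            lig_masses=lig_masses, lig_charges=lig_charges,
            at_pos=at_pos, at_charges=at_charges,
            cg_pos=cg_pos, cg_sigma=coupling.sigma,
            go_sigma=go_sigma, go_epsilon=go_epsilon,
            bonds_i=ii, bonds_j=jj, bonds_r0=bonds_r0, k_intra=k_intra,
            restraints=restraints, anchor_pos=anchor_pos,
            wca_epsilon=coupling.epsilon,
        )

    # -- individual terms (x = ligand coordinates) --------------------------

    def _pair_geometry(self, x, other):
        d = x[:, None, :] - other[None, :, :]
        r = np.linalg.norm(d, axis=-1)
        return d, r

    def intra_energy(self, x) -> float:
        r = np.linalg.norm(x[self.bonds_i] - x[self.bonds_j], axis=1)
        return float(np.sum(self.k_intra * (r - self.bonds_r0) ** 2))

    def intra_forces(self, x) -> np.ndarray:
        d = x[self.bonds_j] - x[self.bonds_i]
        r = np.linalg.norm(d, axis=1)
        coeff = 2.0 * self.k_intra * (r - self.bonds_r0) / r
        pair = coeff[:, None] * d
        f = np.zeros_like(x)
        np.add.at(f, self.bonds_j, -pair)
        np.add.at(f, self.bonds_i, pair)
        return f

    def lj_energy_dudl(self, x, lam_coupling: float):
        _, r = self._pair_geometry(x, self.at_pos)
        u, dudl = softcore_lj(r, self.go_sigma, self.go_epsilon, lam_coupling,
                              self.softcore)
        # CG beads repel through WCA, scaled linearly with the LJ coupling
        _, r_cg = self._pair_geometry(x, self.cg_pos)
        u_cg = wca_energy(r_cg, self.cg_sigma[None, :], self.wca_epsilon)
        return float(u.sum() + lam_coupling * u_cg.sum()), \
            float(dudl.sum() + u_cg.sum())

    def lj_forces(self, x, lam_coupling: float) -> np.ndarray:
        d, r = self._pair_geometry(x, self.at_pos)
        fr = softcore_lj_force(r, self.go_sigma, self.go_epsilon, lam_coupling,
                               self.softcore)
        f = np.sum((fr / np.maximum(r, 1e-12))[:, :, None] * d, axis=1)
        d_cg, r_cg = self._pair_geometry(x, self.cg_pos)
        fr_cg = lam_coupling * wca_force(r_cg, self.cg_sigma[None, :],
                                         self.wca_epsilon)
        f += np.sum((fr_cg / r_cg)[:, :, None] * d_cg, axis=1)
        return f

    def coulomb_energy(self, x) -> float:
        _, r = self._pair_geometry(x, self.at_pos)
        qq = np.outer(self.lig_charges, self.at_charges)
        u = coulomb_rf_energy(r, 1.0, 1.0, self.electrostatics) * qq
        return float(u.sum())

    def coulomb_forces(self, x) -> np.ndarray:
        d, r = self._pair_geometry(x, self.at_pos)
        qq = np.outer(self.lig_charges, self.at_charges)
        fr = coulomb_rf_force(r, 1.0, 1.0, self.electrostatics) * qq
        return np.sum((fr / r)[:, :, None] * d, axis=1)

    def _full_coords(self, x) -> np.ndarray:
        return np.vstack([self.anchor_pos, x])

    def restraint_energy(self, x, lam: float) -> float:
        return boresch_energy(self._full_coords(x), self.restraints, lam)

    def restraint_forces(self, x, lam: float) -> np.ndarray:
        return boresch_forces(self._full_coords(x), self.restraints, lam)[3:]

    def restr_off_analytic(self, temperature: float = 298.0) -> float:
        return boresch_analytic(self.restraints, temperature)


def _spread_indices(points: np.ndarray) -> tuple[int, int, int]:
    """Three mutually distant, non-collinear points of a cluster."""
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    # third point maximizing the triangle area
    cross = np.linalg.norm(
        np.cross(points[j] - points[i], points - points[i]), axis=1
    )
    k = int(np.argmax(cross))
    if cross[k] < 1e-9:
        raise ValueError("ligand atoms are collinear; cannot place anchors")
    return int(i), int(j), k


def _leg_couplings(leg: str, lam: float):
    """(restraint, coulomb, lj) couplings for complex-leg window lam.

    The alchemical variable runs forward through the staging: restraints are
    switched on (0 -> 1), then Coulomb off (1 -> 0), then Lennard-Jones off
    (1 -> 0).  Annihilation would additionally remove intramolecular
    *nonbonded* terms, but the toy ligand has none (its internal structure is
    held by bonds alone, which stay intact on every route), so the
    decoupling and annihilation transformations coincide here by
    construction and differ only in how the ledger is labelled.
    """
    if leg == "restraints":
        return lam, 1.0, 1.0
    if leg == "coulomb":
        return 1.0, 1.0 - lam, 1.0
    if leg == "lj":
        return 1.0, 0.0, 1.0 - lam
    raise ValueError(f"unknown leg {leg!r}; expected one of {LEGS}")


def run_toy_leg(model: ToyComplexModel, leg: str, lambdas=None,
                sim_params: SimulationParams | None = None,
                mode: str = "decoupling") -> TIResult:
    """Run one complex-leg alchemical transformation on the toy model.

    Returns the TI result with the sign convention of the decoupling ledger
    (restraint switching *on* and interactions switching *off* both integrate
    the forward alchemical variable).
    """
    if leg not in LEGS:
        raise ValueError(f"unknown leg {leg!r}; expected one of {LEGS}")
    sim_params = sim_params or SimulationParams(n_steps=20_000, sample_stride=10)
    lambdas = np.linspace(0.0, 1.0, 5) if lambdas is None else np.asarray(lambdas)

    series = []
    for window, lam in enumerate(lambdas):
        c_restr, c_coul, c_lj = _leg_couplings(leg, lam)

        def forces(x, c=(c_restr, c_coul, c_lj)):
            f = model.intra_forces(x)
            f += c[1] * model.coulomb_forces(x)
            f += model.lj_forces(x, c[2])
            f += model.restraint_forces(x, c[0])
            return f

        def potential(x, c=(c_restr, c_coul, c_lj)):
            u_lj, _ = model.lj_energy_dudl(x, c[2])
            return (model.intra_energy(x) + c[1] * model.coulomb_energy(x)
                    + u_lj + model.restraint_energy(x, c[0]))

        def record(x, c=(c_restr, c_coul, c_lj)):
            if leg == "restraints":
                return model.restraint_energy(x, 1.0)
            if leg == "coulomb":
                return -model.coulomb_energy(x)
            _, dudl = model.lj_energy_dudl(x, c[2])
            return -dudl

        system = System(potential=potential, forces=forces,
                        masses=model.lig_masses[:, None], x0=model.lig_x0.copy())
        params = SimulationParams(
            temperature=sim_params.temperature, gamma=sim_params.gamma,
            dt=sim_params.dt, n_steps=sim_params.n_steps,
            seed=sim_params.seed + 7919 * window,
            sample_stride=sim_params.sample_stride,
        )
        result = langevin_run(system, params, record=record,
                              store_trajectory=False)
        series.append(result.series)
    return ti_integrate(series, lambdas)


def run_toy_cycle(model: ToyComplexModel, lambdas_per_leg: dict | None = None,
                  sim_params: SimulationParams | None = None,
                  mode: str = "decoupling"):
    """Full toy binding cycle: three simulated complex legs, analytic rest.

    The toy has no solvent, so both ligand-leg terms vanish identically (the
    isolated ligand couples to nothing); the restraint removal is analytic.
    """
    from .free_energy import assemble_cycle

    lambdas_per_leg = lambdas_per_leg or {}
    terms = {}
    for leg, key in zip(LEGS, ("restr_on_c", "coul_c", "lj_c")):
        ti = run_toy_leg(model, leg, lambdas_per_leg.get(leg), sim_params, mode)
        terms[key] = ti
    terms["coul_l"] = (0.0, 0.0)
    terms["lj_l"] = (0.0, 0.0)
    temperature = (sim_params or SimulationParams()).temperature
    terms["restr_off"] = model.restr_off_analytic(temperature)
    return assemble_cycle(terms, mode=mode)
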