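"""Benchmark free-energy components for lysozyme + tri-N-acetylchitotriose.

Reference thermodynamic-integration results for hen egg-white lysozyme
(HEWL, 129 residues) bound to the inhibitor di-N-acetylchitotriose, computed
with a dual-resolution model (atomistic active site, C-alpha elastic-network
remainder, explicit water) at 3..10 atomistic active-site residues and with
a fully atomistic reference.  All values in kJ/mol as (value, 95% CI
half-width); the restraint-removal term is analytic and carries no
uncertainty.

These numbers serve as a regression anchor for the cycle arithmetic and the
resolution-quality analysis: full-scale explicit-water simulations are not
re-run here.
"""

from __future__ import annotations

from .free_energy import CycleLedger, assemble_cycle
from .mapping_quality import DeviationReport, resolution_scan

__all__ = [
    "COMPLEX_COMPONENTS",
    "LIGAND_COMPONENTS",
    "RESTR_OFF",
    "ANNIHILATION_LEGS",
    "FULLY_ATOMISTIC",
    "benchmark_ledger",
    "benchmark_scan",
]

#: complex-leg components per resolution: (Coulomb, LJ, restraint-on)
FULLY_ATOMISTIC = "fully-at"
COMPLEX_COMPONENTS: dict = {
    FULLY_ATOMISTIC: {"coul_c": (145.2, 3.5), "lj_c": (44.2, 5.2),
                      "restr_on_c": (3.6, 0.4)},
    3: {"coul_c": (125.5, 7.0), "lj_c": (50.4, 6.3), "restr_on_c": (8.3, 1.1)},
    4: {"coul_c": (141.4, 4.9), "lj_c": (39.7, 9.4), "restr_on_c": (7.2, 1.0)},
    5: {"coul_c": (140.2, 2.8), "lj_c": (48.7, 4.5), "restr_on_c": (7.5, 1.2)},
    6: {"coul_c": (147.0, 1.9), "lj_c": (41.7, 5.4), "restr_on_c": (5.1, 0.5)},
    7: {"coul_c": (144.5, 0.8), "lj_c": (38.4, 3.8), "restr_on_c": (5.0, 0.2)},
    8: {"coul_c": (148.0, 1.4), "lj_c": (33.6, 1.9), "restr_on_c": (6.4, 1.8)},
    9: {"coul_c": (143.4, 4.7), "lj_c": (38.1, 5.3), "restr_on_c": (5.1, 0.3)},
    10: {"coul_c": (145.9, 2.2), "lj_c": (38.2, 1.0), "restr_on_c": (4.4, 0.3)},
}

#: ligand solvation leg (resolution independent; ligand always atomistic)
LIGAND_COMPONENTS = {"coul_l": (-142.8, 1.7), "lj_l": (-9.1, 6.3)}

#: analytic Boresch restraint removal to standard state, kJ/mol
RESTR_OFF = -31.3

#: pre-summed legs for the annihilation route (fully atomistic)
ANNIHILATION_LEGS = {
    "espp": {"lig": (-1275.3, 11.2), "compl": (1315.2, 16.3)},
    "grom": {"lig": (-1259.0, 5.9), "compl": (1314.8, 13.2)},
}


def benchmark_ledger(resolution=FULLY_ATOMISTIC, mode: str = "decoupling",
                     engine: str = "espp") -> CycleLedger:
    """Cycle ledger for one benchmark resolution (or the annihilation route)."""
    if mode == "annihilation":
        terms = dict(ANNIHILATION_LEGS[engine])
        terms["restr_off"] = RESTR_OFF
        return assemble_cycle(terms, mode="annihilation")
    terms = dict(COMPLEX_COMPONENTS[resolution])
    terms.update(LIGAND_COMPONENTS)
    terms["restr_off"] = RESTR_OFF
    return assemble_cycle(terms, mode="decoupling")


def benchmark_scan() -> DeviationReport:
    """Deviation report over the benchmark resolutions (n_at = 3..10)."""
    ledgers = {n: benchmark_ledger(n) for n in COMPLEX_COMPONENTS
               if n != FULLY_ATOMISTIC}
    return resolution_scan(ledgers, benchmark_ledger(FULLY_ATOMISTIC))
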