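"""Resolution quality: deviation of free-energy components from the
fully-atomistic reference, and the optimal atomistic residue count.

The total binding free energy is nearly flat in the number of atomistic
residues, but its Coulomb, Lennard-Jones and restraint components are not;
their quadratic deviation from the fully-atomistic reference

    delta_i^2 = (dG_Coul,i - dG_Coul,at)^2 + (dG_LJ,i - dG_LJ,at)^2
                + (dG_Restr,i - dG_Restr,at)^2

exposes an optimal intermediate resolution.  The deviation is unweighted
(uncertainties are ignored) and uses the complex-leg components only, since
the ligand and restraint-removal legs do not depend on protein resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LedgerError
from .free_energy import CycleLedger

__all__ = ["DeviationReport", "quadratic_deviation", "resolution_scan"]

_COMPONENT_KEYS = ("coul_c", "lj_c", "restr_on_c")
_COMPONENT_LABELS = ("coul", "lj", "restr")


def quadratic_deviation(row, reference) -> tuple[float, np.ndarray]:
    """Unweighted squared deviation of a (Coul, LJ, Restr) component triple.

    Returns ``(delta_sq, components)`` where ``components`` holds the three
    squared differences and ``delta_sq`` is their sum.
    """
    row = np.asarray(row, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if row.shape != (3,) or reference.shape != (3,):
        raise ValueError("component triples must have exactly three entries")
    if not (np.all(np.isfinite(row)) and np.all(np.isfinite(reference))):
        raise ValueError("component triples must be finite")
    components = (row - reference) ** 2
    return float(components.sum()), components


@dataclass
class DeviationReport:
    """Per-resolution component deviations and the optimal residue count.

    ``table`` has one row per resolution (sorted by ``n_at``) with the three
    complex-leg components, their squared deviations, ``delta_sq`` and
    ``delta``; ``reference`` holds the fully-atomistic component triple.
    """

    table: pd.DataFrame
    reference: np.ndarray

    @property
    def optimal_n_at(self) -> int:
        """Resolution with the smallest delta; ties favour fewer residues."""
        best = self.table["delta"].min()
        return int(self.table.loc[self.table["delta"] == best, "n_at"].min())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, path=None):
        """delta vs n_at, mirroring the component-deviation scan figure."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.table["n_at"], self.table["delta"], "o-", color="tab:blue")
        ax.axhline(0.0, color="k", lw=0.8, ls="--", label="fully atomistic")
        best = self.optimal_n_at
        ax.axvline(best, color="tab:green", lw=0.8, ls=":",
                   label=f"optimum (n_at={best})")
        ax.set_xlabel("atomistic residues")
        ax.set_ylabel(r"$\delta$ (kJ/mol)")
        ax.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _ledger_triple(ledger: CycleLedger, label: str) -> np.ndarray:
    try:
        return np.array([ledger.component(k)[0] for k in _COMPONENT_KEYS])
    except LedgerError as exc:
        raise LedgerError(f"{label}: {exc}") from None


def resolution_scan(ledgers: dict[int, CycleLedger], reference: CycleLedger
                    ) -> DeviationReport:
    """Scan cycle ledgers over atomistic residue counts against a reference.

    ``ledgers`` maps n_at to the corresponding cycle ledger; ``reference`` is
    the fully-atomistic one.  Every ledger must expose the three complex-leg
    components.  At least two resolutions are required for a scan.
    """
    if len(ledgers) < 2:
        raise ValueError("a resolution scan needs at least two resolutions")
    ref = _ledger_triple(reference, "reference")
    rows = []
    for n_at in sorted(ledgers):
        triple = _ledger_triple(ledgers[n_at], f"n_at={n_at}")
        delta_sq, comps = quadratic_deviation(triple, ref)
        row = {"n_at": n_at}
        row.update({k: v for k, v in zip(_COMPONENT_LABELS, triple)})
        row.update({f"d2_{k}": v for k, v in zip(_COMPONENT_LABELS, comps)})
        row["delta_sq"] = delta_sq
        row["delta"] = float(np.sqrt(delta_sq))
        rows.append(row)
    return DeviationReport(table=pd.DataFrame(rows), reference=ref)
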