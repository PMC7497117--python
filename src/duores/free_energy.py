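"""Thermodynamic integration, block-averaged errors, and the binding cycle.

The binding free energy is assembled from a thermodynamic cycle

    dG_bind = dG_compl + dG_lig + dG_r_off

where the complex leg dG_compl = dG_restr_on,c + dG_coul,c + dG_LJ,c turns
restraints on and protein-ligand interactions off, the ligand leg
dG_lig = dG_coul,l + dG_LJ,l grows the ligand into solvent, and dG_r_off
removes the Boresch restraints analytically (releasing the ligand to the
standard-state volume).  Each simulated term is a TI integral
dG = int_0^1 <dU/dlambda> dlambda evaluated with the trapezoidal rule;
per-lambda uncertainties come from four-block averaging with a Student-t 95%
confidence interval, and component uncertainties combine by linear addition
(a deliberately conservative convention; quadrature summation is available
as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import KB, DEFAULT_TEMPERATURE, STANDARD_VOLUME
from .energetics import BoreschRestraints
from .errors import CoverageError, LedgerError

__all__ = [
    "TIResult",
    "CycleLedger",
    "ti_integrate",
    "block_error",
    "boresch_analytic",
    "assemble_cycle",
]


@dataclass
class TIResult:
    """A thermodynamic-integration estimate over one alchemical leg."""

    lambdas: np.ndarray
    means: np.ndarray          # <dU/dlambda> per lambda, kJ/mol
    errors: np.ndarray         # 95% CI half-widths per lambda, kJ/mol
    dg: float                  # kJ/mol
    dg_error: float            # kJ/mol

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "lambda": self.lambdas, "mean_dudl": self.means,
            "ci95": self.errors,
        })

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path, index=False)


def block_error(series, n_blocks: int = 4, confidence: float = 0.95) -> float:
    """Confidence-interval half-width of a series mean by block averaging.

    The series is split into ``n_blocks`` contiguous equal blocks (trailing
    remainder dropped); the half-width is t_{(1+conf)/2, n-1} * s / sqrt(n)
    with s the sample standard deviation of the block means.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("block_error expects a 1-D series")
    if len(series) < n_blocks:
        raise ValueError(
            f"series of length {len(series)} cannot form {n_blocks} blocks"
        )
    block_len = len(series) // n_blocks
    blocks = series[: n_blocks * block_len].reshape(n_blocks, block_len)
    means = blocks.mean(axis=1)
    s = means.std(ddof=1)
    t = stats.t.ppf(0.5 * (1.0 + confidence), df=n_blocks - 1)
    return float(t * s / np.sqrt(n_blocks))


def ti_integrate(series, lambdas, n_blocks: int = 4, confidence: float = 0.95,
                 allow_partial: bool = False) -> TIResult:
    """Integrate per-lambda dU/dlambda sample series with the trapezoid rule.

    ``series`` is a sequence of 1-D sample arrays, one per lambda.  The
    schedule must be strictly increasing within [0, 1] and include both
    endpoints unless ``allow_partial`` is set (in which case the integral
    covers only the sampled range).  The integral uncertainty is the linear
    sum of |quadrature weight| times the per-lambda half-width.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) < 2:
        raise ValueError("TI needs at least two lambda points")
    if np.any(np.diff(lambdas) <= 0):
        raise ValueError("lambda schedule must be strictly increasing")
    if lambdas[0] < 0 or lambdas[-1] > 1:
        raise ValueError("lambdas must lie within [0, 1]")
    if not allow_partial and (lambdas[0] != 0.0 or lambdas[-1] != 1.0):
        raise CoverageError(
            f"schedule covers [{lambdas[0]}, {lambdas[-1]}], not [0, 1]; "
            "pass allow_partial=True to integrate the sampled range only"
        )
    if len(series) != len(lambdas):
        raise ValueError("one sample series required per lambda")

    means = np.empty(len(lambdas))
    errors = np.empty(len(lambdas))
    for i, s in enumerate(series):
        s = np.asarray(s, dtype=float)
        if s.size == 0:
            raise ValueError(f"empty sample series at lambda={lambdas[i]}")
        means[i] = s.mean()
        errors[i] = block_error(s, n_blocks, confidence) if len(s) >= n_blocks else np.nan

    # trapezoid quadrature weights
    w = np.zeros(len(lambdas))
    gaps = np.diff(lambdas)
    w[:-1] += 0.5 * gaps
    w[1:] += 0.5 * gaps
    dg = float(w @ means)
    dg_error = float(np.abs(w) @ errors)
    return TIResult(lambdas=lambdas, means=means, errors=errors,
                    dg=dg, dg_error=dg_error)


def boresch_analytic(restraints: BoreschRestraints,
                     temperature: float = DEFAULT_TEMPERATURE,
                     standard_volume: float = STANDARD_VOLUME) -> float:
    """Free energy of removing Boresch restraints to the standard state.

    Stiff-spring (Gaussian) closed form:

    dG_r_off = -kT ln[ 8 pi^2 V0 / (r0^2 sin(thetaA0) sin(thetaB0))
                       * sqrt(k_r k_tA k_tB k_pA k_pB k_pC) / (2 pi kT)^3 ]

    with V0 the standard-state volume (1.661 nm^3 at 1 M).  All six force
    constants must be strictly positive (the formula diverges otherwise).
    """
    ks = restraints.force_constants
    if np.any(ks <= 0):
        raise ValueError("all six force constants must be positive")
    sin_a, sin_b = np.sin(restraints.theta_a0), np.sin(restraints.theta_b0)
    if sin_a <= 0 or sin_b <= 0:
        raise ValueError("reference angles must lie strictly inside (0, pi)")
    kt = KB * temperature
    arg = (8.0 * np.pi ** 2 * standard_volume
           / (restraints.r0 ** 2 * sin_a * sin_b)
           * np.sqrt(np.prod(ks)) / (2.0 * np.pi * kt) ** 3)
    return float(-kt * np.log(arg))


# ---------------------------------------------------------------------------
# cycle ledger
# ---------------------------------------------------------------------------

_COMPLEX_COMPONENTS = ("restr_on_c", "coul_c", "lj_c")
_LIGAND_COMPONENTS = ("coul_l", "lj_l")


@dataclass
class CycleLedger:
    """All free-energy terms of the binding cycle, with uncertainties (kJ/mol).

    ``components`` maps term names (restr_on_c, coul_c, lj_c, coul_l, lj_l,
    restr_off) to (value, uncertainty) pairs; leg totals may be supplied
    directly when per-component values are unavailable.  The analytic
    restraint-removal term always carries zero uncertainty.
    """

    mode: str
    components: dict = field(default_factory=dict)
    dg_compl: float = 0.0
    dg_compl_err: float = 0.0
    dg_lig: float = 0.0
    dg_lig_err: float = 0.0
    dg_restr_off: float = 0.0
    dg_bind: float = 0.0
    dg_bind_err: float = 0.0

    def component(self, name: str) -> tuple[float, float]:
        try:
            return self.components[name]
        except KeyError:
            raise LedgerError(f"ledger has no component {name!r}") from None

    def as_dataframe(self):
        import pandas as pd

        rows = [{"term": k, "dg": v, "uncertainty": e}
                for k, (v, e) in self.components.items()]
        rows += [
            {"term": "dg_compl", "dg": self.dg_compl, "uncertainty": self.dg_compl_err},
            {"term": "dg_lig", "dg": self.dg_lig, "uncertainty": self.dg_lig_err},
            {"term": "dg_restr_off", "dg": self.dg_restr_off, "uncertainty": 0.0},
            {"term": "dg_bind", "dg": self.dg_bind, "uncertainty": self.dg_bind_err},
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path, index=False)

    def __str__(self) -> str:
        lines = [f"thermodynamic cycle ({self.mode})"]
        for k, (v, e) in self.components.items():
            lines.append(f"  {k:<12s} {v:10.2f} +/- {e:.2f}")
        lines.append(f"  {'dG_compl':<12s} {self.dg_compl:10.2f} +/- {self.dg_compl_err:.2f}")
        lines.append(f"  {'dG_lig':<12s} {self.dg_lig:10.2f} +/- {self.dg_lig_err:.2f}")
        lines.append(f"  {'dG_r_off':<12s} {self.dg_restr_off:10.2f} (analytic)")
        lines.append(f"  {'dG_bind':<12s} {self.dg_bind:10.2f} +/- {self.dg_bind_err:.2f}")
        return "\n".join(lines)


def _as_value_error(term) -> tuple[float, float]:
    if isinstance(term, TIResult):
        return term.dg, term.dg_error
    if np.isscalar(term):
        return float(term), 0.0
    value, error = term
    return float(value), float(error)


def _combine(errors, how: str) -> float:
    errors = np.asarray(list(errors), dtype=float)
    if how == "linear":
        return float(errors.sum())
    if how == "quadrature":
        return float(np.sqrt((errors ** 2).sum()))
    raise ValueError(f"unknown error combination {how!r}")


def assemble_cycle(terms: dict, mode: str = "decoupling",
                   error_combination: str = "linear") -> CycleLedger:
    """Assemble the binding cycle from leg components or leg totals.

    ``terms`` maps names to values: per-component keys ``restr_on_c``,
    ``coul_c``, ``lj_c`` (complex leg) and ``coul_l``, ``lj_l`` (ligand leg),
    or the pre-summed legs ``compl`` and ``lig``; plus the analytic
    ``restr_off``.  Each value may be a float, a ``(value, error)`` pair, or
    a :class:`TIResult`.  Missing legs raise :class:`LedgerError` naming the
    leg.  Uncertainties combine by linear addition by default.
    """
    if mode not in ("decoupling", "annihilation"):
        raise ValueError(f"mode must be decoupling or annihilation, got {mode!r}")
    components = {k: _as_value_error(v) for k, v in terms.items()}

    def leg(total_key, comp_keys, leg_name):
        if total_key in components:
            return components[total_key]
        missing = [k for k in comp_keys if k not in components]
        if missing:
            raise LedgerError(
                f"{leg_name} leg incomplete: missing {', '.join(missing)} "
                f"(or provide {total_key!r} directly)"
            )
        values, errors = zip(*(components[k] for k in comp_keys))
        return float(np.sum(values)), _combine(errors, error_combination)

    dg_compl, compl_err = leg("compl", _COMPLEX_COMPONENTS, "complex")
    dg_lig, lig_err = leg("lig", _LIGAND_COMPONENTS, "ligand")
    if "restr_off" not in components:
        raise LedgerError("restraint-removal leg missing: provide 'restr_off'")
    dg_restr_off, _ = components["restr_off"]
    components["restr_off"] = (dg_restr_off, 0.0)  # analytic: no uncertainty

    dg_bind = dg_compl + dg_lig + dg_restr_off
    dg_bind_err = _combine([compl_err, lig_err], error_combination)
    return CycleLedger(
        mode=mode, components=components,
        dg_compl=dg_compl, dg_compl_err=compl_err,
        dg_lig=dg_lig, dg_lig_err=lig_err,
        dg_restr_off=dg_restr_off,
        dg_bind=dg_bind, dg_bind_err=dg_bind_err,
    )
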