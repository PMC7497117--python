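"""Flat YAML run configuration with validated, pre-filled defaults.

Every tunable of the pipeline lives in one flat key-value file; unknown keys
are rejected so typos fail loudly.  Defaults follow the dual-resolution
parameterization: stiff backbone springs of 5e4 kJ/(mol nm^2), non-bonded
springs of 160 kJ/(mol nm^2) with a 1.2 nm cutoff, WCA epsilon 0.34 kJ/mol
with scale factor c = 0.658, soft-core alpha = 0.5 and p = 1, reaction-field
dielectric 80 with 1.2 nm cutoff, Langevin friction 15/ps at 298 K with a
1 fs step, and lambda schedules of 11 (restraints), 15 (Coulomb) and 5
(Lennard-Jones) windows on the complex leg and 5/16 on the ligand leg.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "lambda_schedule", "write_provenance"]


def lambda_schedule(n: int, style: str = "endpoint") -> np.ndarray:
    """A lambda grid of n windows in [0, 1].

    ``endpoint``: evenly spaced including 0 and 1 (required for plain TI
    quadrature).  ``midpoint``: n evenly spaced window centres (no
    endpoints), for use with ``allow_partial`` integration.
    """
    if n < 2:
        raise ConfigError("a lambda schedule needs at least two windows")
    if style == "endpoint":
        return np.linspace(0.0, 1.0, n)
    if style == "midpoint":
        return (np.arange(n) + 0.5) / n
    raise ConfigError(f"unknown schedule style {style!r}")


@dataclass
class RunConfig:
    """All knobs of a run; see module docstring for the defaults' provenance."""

    # structure source: a PDB path, or a generated toy complex
    structure: str | None = None
    ligand_selector: list[str] = field(default_factory=lambda: ["LIG"])
    toy_n_residues: int = 20
    toy_seed: int = 1

    # mapping
    n_at: int = 4
    n_at_range: list[int] = field(default_factory=lambda: [3, 10])
    contact_cutoff: float = 0.45

    # elastic network
    k_b: float = 5.0e4
    k_nb: float = 160.0
    r_c: float = 1.2

    # coupling
    epsilon: float = 0.34
    c: float = 0.658

    # alchemy
    alpha: float = 0.5
    p: float = 1.0
    eps_rf: float = 80.0
    r_cut: float = 1.2
    lambdas_restraints: int = 11
    lambdas_coulomb: int = 15
    lambdas_lj: int = 5
    schedule_style: str = "endpoint"
    mode: str = "decoupling"

    # simulation
    temperature: float = 298.0
    gamma: float = 15.0
    dt: float = 0.001
    n_steps: int = 5000
    sample_stride: int = 10
    seed: int = 0

    # terms supplied directly to `cycle` (name -> [value, error])
    terms: dict = field(default_factory=dict)

    out_dir: str = "duores-out"

    def validate(self) -> None:
        problems = []
        if self.structure is not None and not Path(self.structure).exists():
            problems.append(f"structure: file {self.structure!r} does not exist")
        if self.toy_n_residues < 3:
            problems.append("toy_n_residues: must be >= 3")
        if self.n_at < 0:
            problems.append("n_at: must be >= 0")
        if not (len(self.n_at_range) == 2 and 0 <= self.n_at_range[0] <= self.n_at_range[1]):
            problems.append("n_at_range: must be [lo, hi] with 0 <= lo <= hi")
        for key in ("contact_cutoff", "k_b", "r_c", "epsilon", "c", "p",
                    "r_cut", "temperature", "dt"):
            if getattr(self, key) <= 0:
                problems.append(f"{key}: must be positive")
        for key in ("k_nb", "alpha", "gamma"):
            if getattr(self, key) < 0:
                problems.append(f"{key}: must be non-negative")
        if self.eps_rf < 1:
            problems.append("eps_rf: must be >= 1")
        for key in ("lambdas_restraints", "lambdas_coulomb", "lambdas_lj"):
            if getattr(self, key) < 2:
                problems.append(f"{key}: must be >= 2")
        if self.schedule_style not in ("endpoint", "midpoint"):
            problems.append("schedule_style: must be 'endpoint' or 'midpoint'")
        if self.mode not in ("decoupling", "annihilation"):
            problems.append("mode: must be 'decoupling' or 'annihilation'")
        if self.n_steps < 1 or self.sample_stride < 1:
            problems.append("n_steps and sample_stride must be >= 1")
        if problems:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))

    def schedules(self) -> dict[str, np.ndarray]:
        return {
            "restraints": lambda_schedule(self.lambdas_restraints, "endpoint"),
            "coulomb": lambda_schedule(self.lambdas_coulomb, "endpoint"),
            "lj": lambda_schedule(self.lambdas_lj, self.schedule_style),
        }


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; missing file/keys fall back to defaults."""
    data: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    data.update(overrides or {})
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def write_provenance(cfg: RunConfig, out_dir: Path, command: str) -> None:
    """Record config hash, seed and library versions next to the outputs."""
    import duores

    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    provenance = {
        "command": command,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "duores": duores.__version__,
            "numpy": np.__version__,
        },
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
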