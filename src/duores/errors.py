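"""Exception hierarchy.

Every error raised on purpose by the library derives from :class:`DuoresError`
so callers (and the CLI) can distinguish anticipated failures from bugs.
"""


class DuoresError(Exception):
    """Base class for all duores errors."""


class PDBParseError(DuoresError):
    """A PDB file could not be parsed (message names the offending line)."""


class StructureError(DuoresError):
    """A structure violates a structural requirement (e.g. missing C-alpha)."""


class LigandMissingError(StructureError):
    """An operation requiring a ligand was called on a ligand-free structure."""


class MappingError(DuoresError):
    """Inconsistent atomistic/coarse-grained residue partition."""


class IllConditionedNetworkError(DuoresError):
    """An elastic network has more soft modes than rigid-body motions allow."""


class GeometryError(DuoresError):
    """Degenerate geometry (e.g. collinear restraint anchors)."""


class CalibrationError(DuoresError):
    """Root bracketing / calibration failed."""


class CoverageError(DuoresError):
    """A lambda schedule does not cover both endpoints of the alchemical path."""


class LedgerError(DuoresError):
    """A thermodynamic-cycle ledger is missing a required term."""


class DivergenceError(DuoresError):
    """A simulation produced non-finite coordinates or energies."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite state at step {step}")


class ConfigError(DuoresError):
    """Invalid run configuration."""
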