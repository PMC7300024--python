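"""Exception hierarchy shared across the package."""


class TmrepackError(Exception):
    """Base class for all package errors."""


class PDBParseError(TmrepackError):
    """A coordinate line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructureError(TmrepackError):
    """Inconsistent structure content (e.g. atom count differs across MODELs)."""


class PDBFormatError(TmrepackError):
    """A record cannot be represented in fixed-column PDB format."""


class SelectionError(TmrepackError):
    """Base for selection failures."""


class UnknownSelectionError(SelectionError):
    """Named group does not exist in the selection config."""


class EmptySelectionError(SelectionError):
    """Selection resolved to zero atoms."""


class DegenerateAxisError(TmrepackError):
    """Principal-axis fit is ambiguous (near-isotropic point cloud)."""


class InsufficientDataError(TmrepackError):
    """Not enough frames/blocks/atoms for the requested statistic."""


class CapacityError(TmrepackError):
    """Region too small to hold the requested number of waters."""


class NonUniformSpacingError(TmrepackError):
    """Trajectory frame times are not uniformly spaced."""
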