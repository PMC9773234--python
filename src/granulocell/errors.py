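"""Exception types shared across the package."""


class GranulocellError(Exception):
    """Base class for package errors."""


class PlacementError(GranulocellError):
    """Could not place the requested particles without overlap."""


class RelaxationError(GranulocellError):
    """A relaxation loop did not converge within its step budget."""

    def __init__(self, message: str, final_metric: float | None = None):
        super().__init__(message)
        self.final_metric = final_metric


class DegenerateGeometryError(GranulocellError):
    """Coincident centres or another geometry without a defined normal."""


class BondStateError(GranulocellError):
    """Illegal bond state transition or query."""


class ConfigError(GranulocellError):
    """Invalid or unknown configuration values."""


class UnbondedCellError(GranulocellError):
    """The cell has no engaged bonds and therefore cannot spread."""
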