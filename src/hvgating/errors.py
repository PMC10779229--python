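"""Exception hierarchy shared across the package."""


class HvGatingError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HvGatingError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSchemeError(InvalidInputError):
    """The kinetic scheme is reducible or otherwise ill-posed."""


class InvalidWindowError(InvalidInputError):
    """A time window lies outside the sweep or is empty."""


class FitFailureError(HvGatingError, RuntimeError):
    """Nonlinear fit did not converge; carries the best candidate found.

    Attributes
    ----------
    best : object or None
        The best (lowest residual) fit result obtained before giving up.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class SchemaError(HvGatingError, ValueError):
    """Tabular input is missing a required column or has wrong dtype."""


class DataError(HvGatingError, ValueError):
    """Tabular input is structurally valid but semantically broken."""


class FormatError(HvGatingError, ValueError):
    """A structure file violates the expected multi-model layout."""


class SelectionError(InvalidInputError):
    """An atom selection matched nothing or used an unknown keyword."""


class DegenerateGeometryError(InvalidInputError):
    """Too few / collinear atoms for a rigid-body superposition."""


class GenerationError(HvGatingError, RuntimeError):
    """A synthetic-data generator received an infeasible specification."""
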