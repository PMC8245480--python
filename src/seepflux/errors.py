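"""Exception hierarchy shared by all pipeline stages."""


class SeepfluxError(Exception):
    """Base class for all seepflux errors."""


class InvalidInputError(SeepfluxError, ValueError):
    """An argument violates a precondition (wrong sign, shape, range...)."""


class InsufficientDataError(SeepfluxError, ValueError):
    """Too few observations to perform the requested fit or summary."""


class DegenerateDesignError(SeepfluxError, ValueError):
    """The design matrix is singular, e.g. all time points identical."""


class OutOfRangeError(SeepfluxError, ValueError):
    """A value lies outside the calibrated / defined interval."""


class InvalidPolygonError(SeepfluxError, ValueError):
    """A region of interest is not a simple polygon or lies out of bounds."""


class AssociationError(SeepfluxError, ValueError):
    """A negative (mat-free) ROI is not contained in any rock ROI."""


class SchemaError(SeepfluxError, ValueError):
    """A tabular input file does not match the expected column schema."""
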