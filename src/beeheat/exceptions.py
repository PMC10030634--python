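"""Exception types raised across the package."""


class BeeHeatError(Exception):
    """Base class for all beeheat errors."""


class DomainError(BeeHeatError, ValueError):
    """A physical quantity is outside its admissible domain
    (temperature at/below absolute zero, negative area, negative flux...)."""


class VariantMismatchError(BeeHeatError, ValueError):
    """A coefficient set was used with an operation that does not
    support its model variant."""


class CollinearityError(BeeHeatError, ValueError):
    """The design matrix is rank deficient; carries the names of the
    columns involved in the dependency."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"design matrix is rank deficient; collinear columns: {self.columns}"
        )


class ValidationError(BeeHeatError, ValueError):
    """Malformed input data (bad file header, unparseable cell, ...)."""
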