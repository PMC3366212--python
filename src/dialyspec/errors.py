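"""Exception hierarchy shared across the pipeline stages."""


class DialyspecError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DialyspecError, ValueError):
    """A configuration or filter parameter violates its constraints."""


class InvalidInputError(DialyspecError, ValueError):
    """Input data violates a precondition (empty split, short grid, ...)."""


class CollinearityError(DialyspecError, ValueError):
    """Design matrix is rank deficient; names the offending wavelengths."""

    def __init__(self, wavelengths, message=None):
        self.wavelengths = list(wavelengths)
        super().__init__(
            message
            or f"rank-deficient design matrix for wavelengths {self.wavelengths}"
        )


class KindMismatchError(DialyspecError, ValueError):
    """Signal kind of a spectrum does not match what the consumer expects."""


class GridError(DialyspecError, ValueError):
    """Wavelength grid does not cover or match what an operation needs."""


class SchemaError(DialyspecError, ValueError):
    """A file's structure does not match the declared schema."""
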