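"""Exception types shared across the package."""


class AnionPumpError(Exception):
    """Base class for package errors."""


class ValidationError(AnionPumpError, ValueError):
    """An input object or scenario violates its invariants."""


class FormatError(AnionPumpError, ValueError):
    """A file could not be parsed into the expected structure."""


class SingularTransformError(AnionPumpError, ValueError):
    """The DADS/SADS linear map is singular (coincident time constants)."""


class NoSignalError(AnionPumpError, ValueError):
    """A series carries no titratable signal above the noise floor."""
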