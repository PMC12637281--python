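"""Exception and warning types shared across the package."""


class SpinpolError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpinpolError, ValueError):
    """A file did not conform to the expected on-disk format."""


class ValidationError(SpinpolError, ValueError):
    """An input violated a documented invariant or precondition."""


class FitError(SpinpolError, RuntimeError):
    """A fitting routine failed to produce a usable result."""


class TruncationWarning(UserWarning):
    """Simulated resonance lines fell outside the requested field range."""
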