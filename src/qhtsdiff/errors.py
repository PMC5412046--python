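"""Exception types shared across the package."""


class QhtsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QhtsError):
    """Invalid generator or pipeline configuration."""


class NormalizationError(QhtsError):
    """Raw-signal normalization cannot proceed (e.g. no vehicle controls)."""


class FitError(QhtsError):
    """A dose-response curve cannot be fitted (e.g. too few points)."""


class DataError(QhtsError):
    """Malformed or inconsistent input tables."""
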