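"""Exception hierarchy shared across the package."""


class TwinScanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TwinScanError, ValueError):
    """A text input (motion-parameter file, table) could not be parsed."""


class ValidationError(TwinScanError, ValueError):
    """An input violates a structural contract (codes, duplicates, flags)."""


class InsufficientDataError(TwinScanError, ValueError):
    """Too few observations to compute the requested quantity."""


class DegenerateDataError(TwinScanError, ValueError):
    """The data are degenerate for the requested statistic (e.g. zero variance)."""
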