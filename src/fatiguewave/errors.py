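"""Exception types shared across the pipeline."""


class FatigueWaveError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(FatigueWaveError, ValueError):
    """Raised when an input is constant / zero-variance where variation is required."""


class DegenerateProfileError(FatigueWaveError, ValueError):
    """Raised when a band-energy profile has zero total energy."""


class SchemaError(FatigueWaveError, ValueError):
    """Raised when a table is missing required columns or structure."""
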