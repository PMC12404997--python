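"""Exception types shared across the package."""


class ConfinequantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ConfinequantError, ValueError):
    """A configuration, schedule or argument violates its invariants."""


class GeometryError(ConfinequantError, ValueError):
    """A geometric precondition fails (canvas too small, path out of bounds,
    degenerate object after erosion, ...)."""


class CalibrationError(ConfinequantError, ValueError):
    """Pixel size or frame interval is missing and no override was given."""


class SchemaError(ConfinequantError, KeyError):
    """A tabular input is missing required columns."""
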