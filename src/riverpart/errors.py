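"""Exception hierarchy shared across the package."""


class RiverpartError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RiverpartError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(RiverpartError, KeyError):
    """A required column is missing or unknown."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class DegenerateInputError(RiverpartError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero variance)."""


class EmptyPresenceError(RiverpartError, ValueError):
    """Occupancy is zero everywhere; no presences can be simulated."""


class InsufficientBackgroundError(RiverpartError, ValueError):
    """Too few eligible reaches to draw the requested background sample."""


class UndefinedMetricError(RiverpartError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""
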