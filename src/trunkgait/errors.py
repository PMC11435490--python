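"""Exception hierarchy for the trunkgait pipeline."""


class TrunkGaitError(Exception):
    """Base class for all trunkgait errors."""


class FormatError(TrunkGaitError):
    """A file does not match the documented schema (missing columns, bad header)."""


class SamplingError(TrunkGaitError):
    """Non-uniform or invalid sampling of an acceleration trace."""


class SchemaError(TrunkGaitError):
    """Inconsistent column sets across result rows."""


class InconsistencyError(TrunkGaitError):
    """A declared group label contradicts the NLR threshold rule."""


class ConfigError(TrunkGaitError):
    """Run configuration violates its invariants."""


class LengthError(TrunkGaitError):
    """Signal too short for the requested operation."""


class InsufficientGaitError(TrunkGaitError):
    """Too few (or too irregular) gait events detected in a trace."""


class InsufficientStridesError(TrunkGaitError):
    """Fewer retained strides than the configured minimum."""

    def __init__(self, retained: int, minimum: int):
        self.retained = retained
        self.minimum = minimum
        super().__init__(f"{retained} < {minimum} retained strides")


class LabellingError(TrunkGaitError):
    """Paretic-side information missing where a side-referenced output is requested."""


class DegenerateSeriesError(TrunkGaitError):
    """Series is constant or otherwise unusable for state-space analysis."""


class EstimationError(TrunkGaitError):
    """Too few neighbour pairs (or similar) for a stable estimate."""


class EmptyResultError(TrunkGaitError):
    """Every stride was skipped; nothing to aggregate."""


class DomainError(TrunkGaitError):
    """Input outside the mathematical domain of a formula."""
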