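"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`BridgeSwitchError`
so callers can catch pipeline failures with a single except clause while still
discriminating the stage that failed.
"""


class BridgeSwitchError(Exception):
    """Base class for all package errors."""


class PDBParseError(BridgeSwitchError):
    """Unparseable PDB content; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TopologyMismatchError(BridgeSwitchError):
    """A model's atoms differ from the first model's topology."""


class SchemaError(BridgeSwitchError):
    """A tabular file is missing a required column or metadata field."""


class SeriesValidationError(BridgeSwitchError):
    """A time series violates its invariants (ordering, sign, length)."""


class EmptyAnalysisError(BridgeSwitchError):
    """No frames remain after filtering; nothing to analyse."""


class AlignmentError(BridgeSwitchError):
    """Two series that must share a time axis do not."""


class UndefinedCorrelationError(BridgeSwitchError):
    """Correlation requested on a constant series."""


class DegenerateGeometryError(BridgeSwitchError):
    """Too few or collinear atoms for a rigid superposition."""


class InsufficientDataError(BridgeSwitchError):
    """Not enough frames/points for the requested statistic."""


class ParameterError(BridgeSwitchError):
    """An argument violates its precondition (thresholds, block length...)."""


class SelectionError(BridgeSwitchError):
    """An atom selection matched nothing usable."""


class GroupLookupError(BridgeSwitchError):
    """A charged group references atoms absent from the frame."""


class ConfigValidationError(BridgeSwitchError):
    """An analysis configuration references entities not present in the input."""
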