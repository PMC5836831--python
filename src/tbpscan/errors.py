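"""Exception hierarchy for tbpscan.

All package-specific failures derive from :class:`TbpScanError` so callers can
catch one base class; most also derive from ``ValueError`` because they signal
invalid input rather than internal state.
"""


class TbpScanError(Exception):
    """Base class for all tbpscan errors."""


class AlphabetError(TbpScanError, ValueError):
    """Sequence contains characters outside the A/C/G/T alphabet."""


class BoundaryError(TbpScanError, ValueError):
    """Requested promoter region extends past the sequence boundary."""


class WindowLengthError(TbpScanError, ValueError):
    """Sequence or window length incompatible with the model window."""


class ContextNotFoundError(TbpScanError, ValueError):
    """Variant flank context does not occur in the target region."""


class AmbiguousContextError(TbpScanError, ValueError):
    """Variant flank context occurs more than once in the target region."""


class InsertResolutionError(TbpScanError, KeyError):
    """A symbolic allele name could not be resolved to a sequence."""


class MarkerTableError(TbpScanError, ValueError):
    """Malformed row in a marker table; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CalibrationRankError(TbpScanError, ValueError):
    """Calibration system is underdetermined (too few or degenerate data)."""


class CalibrationConvergenceError(TbpScanError, RuntimeError):
    """Best-window assignment did not stabilise within the iteration cap."""


class DegenerateDataError(TbpScanError, ValueError):
    """Statistic undefined on the given data (all ties / zero variance)."""


class GenerationError(TbpScanError, RuntimeError):
    """Synthetic-case search exhausted its candidate budget."""
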