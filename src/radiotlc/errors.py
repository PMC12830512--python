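"""Exception hierarchy for the radiotlc package.

All package-specific failures derive from :class:`RadioTLCError` so callers
can catch one base class.  Validation-type errors additionally derive from
:class:`ValueError` for interoperability with generic error handling.
"""


class RadioTLCError(Exception):
    """Base class for all radiotlc errors."""


class InvalidParameterError(RadioTLCError, ValueError):
    """A parameter violates its documented precondition."""


class ParseError(RadioTLCError, ValueError):
    """An acquisition record (or region file) could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class IntegrityError(RadioTLCError):
    """A record with a failed SHA-256 footprint was offered for analysis."""


class AnalysisError(RadioTLCError, ValueError):
    """Base class for chromatogram-analysis errors."""


class InsufficientBaselineError(AnalysisError):
    """Background region contains fewer than two channels."""


class RegionBoundsError(AnalysisError):
    """Integration region falls (partly) outside the scanned range."""


class UndefinedPercentageError(AnalysisError):
    """All net areas are non-positive; relative percentages are undefined."""


class InvalidMarksError(AnalysisError):
    """Solvent front mark does not lie beyond the origin mark."""


class UndefinedFWHMError(AnalysisError):
    """Peak not above baseline, or a half-maximum crossing left the region."""


class UndefinedCVError(RadioTLCError, ValueError):
    """Coefficient of variation undefined (zero mean)."""


class UndefinedCorrelationError(RadioTLCError, ValueError):
    """Pearson correlation undefined (a series has zero variance)."""


class InvalidRangeError(RadioTLCError, ValueError):
    """Derived working-range lower limit is not below the upper limit."""


class PeakMatchingError(RadioTLCError):
    """Detected peak count does not match the expected spot layout."""
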