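"""Exception types raised by the scoring and audit machinery."""


class PscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(PscoreError, ValueError):
    """Input violates a structural contract (shape, labels, finiteness)."""


class DegenerateDistributionError(PscoreError, ValueError):
    """A reference column cannot anchor percentile-edge scores.

    Raised when the distance from the median to a percentile edge is zero
    (at least half of the column equals the edge, e.g. a constant column)
    or when a column has zero sample standard deviation. Scores are refused
    outright rather than emitted as NaN: silent NaNs would corrupt the
    extreme-value tail counts the method is designed to audit.
    """

    def __init__(self, message: str, roi_label: str | None = None):
        super().__init__(message)
        self.roi_label = roi_label
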