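"""Exception hierarchy.

All package errors derive from :class:`SoftGaitError` so callers can catch
one base class; the CLI maps the three branches to distinct exit codes.
"""


class SoftGaitError(Exception):
    """Base class for all softgait errors."""


class ParseError(SoftGaitError):
    """A file could not be parsed (bad header, non-numeric cell, empty input)."""


class ValidationError(SoftGaitError):
    """An in-memory object violates a domain invariant."""


class ParameterError(ValidationError):
    """Simulation or algorithm parameters are out of their valid range."""


class ConsistencyError(ValidationError):
    """Session metadata and trace disagree (e.g. trace shorter than the walk)."""


class StatisticsError(SoftGaitError):
    """A statistical routine received degenerate input (constant vector,
    all-zero differences, rank-deficient design, too few observations)."""
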