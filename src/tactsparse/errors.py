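"""Exception hierarchy.

Validation failures name the offending field so CLI users can fix config
files without reading tracebacks.
"""


class TactsparseError(Exception):
    """Base class for all package errors."""


class ParameterError(TactsparseError, ValueError):
    """A model or algorithm parameter violates its invariant."""


class ValidationError(TactsparseError, ValueError):
    """A data structure is internally inconsistent (shape/type/range)."""


class DegenerateInputError(TactsparseError, ValueError):
    """An input is degenerate for the requested statistic (e.g. zero mean)."""
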