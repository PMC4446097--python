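"""Exception hierarchy for splicecons.

All validation problems raise :class:`ValidationError` (a ``ValueError``),
numerical/degeneracy problems raise :class:`NumericalError` subclasses, so
callers (and the CLI exit-code mapping) can distinguish bad input from a
failed computation.
"""


class SpliceconsError(Exception):
    """Base class for all package errors."""


class ValidationError(SpliceconsError, ValueError):
    """Invalid input: bad configuration field, malformed file, unknown id."""


class DegenerateDataError(SpliceconsError, ValueError):
    """Data carry no information for the requested operation
    (all scores identical, all sharing counts equal, ...)."""


class BoundaryError(SpliceconsError, ValueError):
    """The MLE lies on the parameter-space boundary (no interior optimum)."""


class ConvergenceError(SpliceconsError, RuntimeError):
    """An iterative fit or bootstrap failed to converge reliably."""
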