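"""Exception hierarchy for the biosorb package.

Every error path raises a subclass of :class:`BiosorbError`, so callers
(and the CLI) can map failures onto distinct categories and exit codes.
"""


class BiosorbError(Exception):
    """Base class for all biosorb errors."""


class InvalidRecordError(BiosorbError, ValueError):
    """A batch sorption record violates its physical invariants."""


class UndefinedRatioError(BiosorbError, ZeroDivisionError):
    """Removal ratio requested for a zero initial concentration."""


class DomainError(BiosorbError, ValueError):
    """An argument is outside its physical domain (e.g. negative concentration)."""


class InvalidLevelError(BiosorbError, ValueError):
    """The h-certain factor is outside [0, 1)."""


class ShapeError(BiosorbError, ValueError):
    """Dimension mismatch between a model and a predictor vector."""


class UndefinedR2Error(BiosorbError, ValueError):
    """Coefficient of determination undefined (constant response)."""


class SolverError(BiosorbError, RuntimeError):
    """The LP or root-finding backend failed; carries solver diagnostics."""


class OracleSizeError(BiosorbError, ValueError):
    """Instance too large for the exhaustive vertex-enumeration oracle."""


class DegeneratePointError(BiosorbError, ValueError):
    """An isotherm point cannot be linearized (non-positive Ce or Qe)."""


class NonInvertibleFitError(BiosorbError, ValueError):
    """A fuzzy coefficient support touches zero, so interval inversion fails.

    The fitted fuzzy model is still attached as ``.model`` for reporting.
    """

    def __init__(self, message: str, model=None):
        super().__init__(message)
        self.model = model


class ConfigError(BiosorbError, ValueError):
    """Invalid run configuration."""


class ParseError(BiosorbError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
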