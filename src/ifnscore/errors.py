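"""Exception hierarchy shared across the package."""


class IfnScoreError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IfnScoreError, ValueError):
    """An input file violates the expected dialect (missing column, bad header...)."""


class ParseError(IfnScoreError, ValueError):
    """A cell could not be parsed; the message names the offending row/column."""


class ValidationError(IfnScoreError, ValueError):
    """Arguments or data violate a documented precondition."""


class ComputationError(IfnScoreError, RuntimeError):
    """A numerical procedure failed (e.g. a curve fit did not converge)."""
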