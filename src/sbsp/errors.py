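"""Exception hierarchy shared across the package."""


class SBSPError(Exception):
    """Base class for package-specific failures."""


class FormatError(SBSPError, ValueError):
    """A file could not be parsed under the requested dialect.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SBSPError, ValueError):
    """Parsed data violates a model invariant (e.g. a non-binary entry)."""


class DegenerateDataError(SBSPError, ValueError):
    """Data with no observed features: the marginal likelihood is maximized
    on the parameter boundary, so empirical-Bayes fitting refuses to run."""
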