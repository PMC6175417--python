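"""Exception hierarchy shared across the package."""


class ResurveyError(Exception):
    """Base class for all package errors."""


class SchemaError(ResurveyError):
    """An input table is missing a required column or has an unusable header."""


class ValidationError(ResurveyError):
    """A value violates a domain constraint (e.g. cover outside [0, 100])."""


class ConsistencyError(ResurveyError):
    """Cross-row constraints violated (e.g. one plot mapped to two blocks)."""


class EmptyDatasetError(ResurveyError):
    """Filtering removed every plot or record."""


class ConfigError(ResurveyError):
    """A simulation or pipeline configuration is invalid."""


class ConvergenceError(ResurveyError):
    """A model backend failed to converge; carries backend diagnostics."""

    def __init__(self, message: str, diagnostics: object = None):
        super().__init__(message)
        self.diagnostics = diagnostics


class UndefinedResultError(ResurveyError):
    """A quantity is undefined for the given input (e.g. zero denominator)."""
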