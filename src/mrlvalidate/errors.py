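"""Exception hierarchy shared across the package."""


class MrlValidateError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MrlValidateError):
    """An input table is missing required columns or has malformed values."""


class DuplicateTransitionError(SchemaError):
    """The same (analyte, precursor, product) transition appears twice."""


class ConfigError(MrlValidateError):
    """A simulation or pipeline configuration violates its invariants."""


class InsufficientDataError(MrlValidateError):
    """Too few levels/replicates/days for the requested statistic."""


class MissingLevelError(MrlValidateError):
    """A spike level has no matching standard records."""


class NotDetectableError(MrlValidateError):
    """Quantifier signal absent; a ratio or CV is undefined."""
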