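"""Exception hierarchy for assayunc."""


class AssayUncError(Exception):
    """Base class for all assayunc errors."""


class InvalidInputError(AssayUncError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(AssayUncError, ValueError):
    """Too few observations to evaluate the requested quantity."""


class SingularFitError(AssayUncError, ArithmeticError):
    """A regression or inverse prediction is degenerate (zero slope, no x spread)."""


class ConfigError(AssayUncError, ValueError):
    """An assay configuration file or scheme definition is invalid."""
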