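"""Exception hierarchy shared across the package."""


class PeatVpdError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PeatVpdError, ValueError):
    """An input violates a documented precondition (range, finiteness, units)."""


class DegenerateInputError(PeatVpdError, ValueError):
    """Numerically degenerate input (e.g. vanishing log term, zero variance)."""


class SingularDesignError(PeatVpdError, ValueError):
    """Regression design matrix is singular (constant regressor, collinearity)."""


class AlignmentError(PeatVpdError, ValueError):
    """Grids or paired series do not share coordinates / length."""


class EmptyRegionError(PeatVpdError, ValueError):
    """A regional mask selects no valid pixels."""


class SchemaError(PeatVpdError, ValueError):
    """A file is missing mandatory columns or attributes."""


class ModelGateError(PeatVpdError, RuntimeError):
    """A downstream quantity was requested from a model that failed its
    validation gate (e.g. held-out r below threshold)."""


class DegenerateFitError(PeatVpdError, ValueError):
    """Model fitting is impossible (e.g. constant response)."""
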