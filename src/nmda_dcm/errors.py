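"""Exception hierarchy shared across the package."""


class ModelError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ModelError, ValueError):
    """A parameter value violates its domain (non-finite, wrong sign, ...)."""


class StructuralError(ModelError, ValueError):
    """Shapes or layouts of two objects that must agree do not."""


class IntegrationDivergenceError(ModelError, RuntimeError):
    """The ODE integration blew up for a particular parameter draw."""


class ERPFormatError(ModelError, ValueError):
    """An evoked-response file or sidecar is malformed."""


class InversionFailureError(ModelError, RuntimeError):
    """Model inversion could not take a single valid step."""


class DesignError(ModelError, ValueError):
    """A second-level design matrix is unusable (e.g. rank deficient)."""


class DegenerateDataError(ModelError, ValueError):
    """A statistic is undefined for these data (e.g. zero-variance differences)."""
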