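"""Exception hierarchy shared across the package."""


class MD2BDError(Exception):
    """Base class for all package errors."""


class ParameterError(MD2BDError, ValueError):
    """A model parameter is out of its admissible range."""


class ConfigurationError(MD2BDError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class GeometryError(MD2BDError, ValueError):
    """A geometric precondition is violated (non-unit normal, disjoint windows, ...)."""


class StateError(MD2BDError, ValueError):
    """A simulation state is invalid (e.g. interpenetrating particles)."""


class StepSizeError(MD2BDError, RuntimeError):
    """The time step is too large for the event-resolution assumptions."""


class NumericalError(MD2BDError, RuntimeError):
    """An optimizer or quadrature failed to converge."""
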