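"""Exception hierarchy shared across the package."""


class PermCleanError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PermCleanError, ValueError):
    """A configuration or algorithm parameter is invalid."""


class InputError(PermCleanError, ValueError):
    """Input data violates a precondition (shape, grid, emptiness)."""


class StateError(PermCleanError, RuntimeError):
    """A streaming operation was called in an invalid state."""
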