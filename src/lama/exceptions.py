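"""Exception hierarchy shared across the package."""


class LamaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LamaError, ValueError):
    """A specification or input failed its invariants."""


class SelectionError(LamaError, ValueError):
    """An atom-selection expression failed to parse or resolved to nothing."""


class FormatError(LamaError, ValueError):
    """A trajectory or topology file could not be parsed."""


class SimulationError(LamaError, RuntimeError):
    """A synthetic simulation left its declared domain."""
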