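"""Exception hierarchy shared across the toolkit."""


class RootFOSError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(RootFOSError, ValueError):
    """A numeric parameter is outside its physically sane range."""


class GeometryError(RootFOSError, ValueError):
    """Device geometry is inconsistent (e.g. spiral exceeds the pot)."""


class ProcessingError(RootFOSError, ValueError):
    """A signal-processing stage cannot run on the given record."""


class ParseError(RootFOSError, ValueError):
    """Delimited input could not be parsed into a valid record."""


class SimulationError(RootFOSError, ValueError):
    """A scenario is inconsistent or lacks a seed for stochastic terms."""


class DegenerateMeshError(RootFOSError, ValueError):
    """A radius profile has no material to revolve into a surface."""
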