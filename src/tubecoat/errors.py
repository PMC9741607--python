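"""Exception hierarchy shared across tubecoat modules."""


class TubecoatError(Exception):
    """Base class for all tubecoat errors."""


class ValidationError(TubecoatError, ValueError):
    """Invalid input data or domain violation (bad radius, angle, table)."""


class ConfigurationError(TubecoatError, ValueError):
    """Inconsistent model configuration (e.g. all elastic weights zero)."""


class FittingError(TubecoatError, RuntimeError):
    """A least-squares fit could not be performed or did not converge."""


class InsufficientExtentError(FittingError):
    """A filament trace spans too little azimuth to determine its pitch."""
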