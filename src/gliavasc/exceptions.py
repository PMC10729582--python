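"""Exception types shared across the pipeline stages."""


class GliavascError(Exception):
    """Base class for package errors."""


class ConfigurationError(GliavascError, ValueError):
    """A configuration value is missing, unknown, or out of bounds."""


class PlacementError(GliavascError, RuntimeError):
    """Synthetic cells could not be placed without overlap after bounded retries."""


class DegenerateDistributionError(GliavascError, ValueError):
    """An intensity distribution has too few distinct values to threshold."""


class InconsistencyError(GliavascError, RuntimeError):
    """An internal contract between pipeline stages was violated."""
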