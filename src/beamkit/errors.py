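"""Exception hierarchy shared across the toolkit."""


class BeamkitError(Exception):
    """Base class for all beamkit errors."""


class MaterialNotFoundError(BeamkitError, LookupError):
    """An element or compound identifier could not be resolved."""


class DataValidationError(BeamkitError, ValueError):
    """Input data violates a documented invariant (schema, sign, shape...)."""


class OutOfRangeError(BeamkitError, ValueError):
    """A query falls outside the tabulated range; no silent extrapolation."""


class ZeroDoseError(DataValidationError):
    """A dose-normalized quantity was requested for a zero-dose spectrum."""


class ConfigurationError(BeamkitError):
    """A required piece of configuration (e.g. scale factors) is missing."""
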