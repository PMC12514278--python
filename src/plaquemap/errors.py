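"""Package exception hierarchy."""


class PlaquemapError(Exception):
    """Base class for package errors."""


class ConfigurationError(PlaquemapError, ValueError):
    """Invalid configuration (unknown severity, bad mixture, empty design...)."""


class ParameterError(PlaquemapError, ValueError):
    """Invalid analysis parameter (negative radius, k < 2, n_pc <= 0...)."""


class DataError(PlaquemapError, ValueError):
    """Input data violates a precondition (zero-total cell, no negative probes...)."""
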