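"""Exception hierarchy.

Configuration errors (bad inputs, missing coefficients, out-of-range
design points) are distinguished from numerical failures (non-finite
temperatures, integration leaving the physiological band, singular RBF
systems) so callers and the pipeline can exit with different codes.
"""


class CabthermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CabthermError):
    """Invalid or incomplete configuration / inputs."""


class RangeError(ConfigurationError):
    """A design factor lies outside its declared range."""


class NumericalError(CabthermError):
    """A numerical failure (non-finite value, singular system)."""


class IntegrationError(NumericalError):
    """The thermoregulation solver left the physiological band."""
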