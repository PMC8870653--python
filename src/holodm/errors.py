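"""Exception hierarchy shared across the package.

Configuration problems (bad parameters, invalid geometry) raise
:class:`ConfigError`; problems with the data itself (missing sideband,
malformed files) raise :class:`DataError`.  The CLI maps these to exit
codes 2 and 3 respectively.
"""


class HolodmError(Exception):
    """Base class for all package errors."""


class ConfigError(HolodmError, ValueError):
    """Invalid parameter or configuration."""


class DataError(HolodmError, RuntimeError):
    """Input data violates an assumption of the algorithm."""


class AliasingError(ConfigError):
    """Carrier frequency at or above the Nyquist limit."""


class NoSidebandError(DataError):
    """No off-axis sideband found in the hologram spectrum."""


class MaskOverlapError(ConfigError):
    """Sideband mask would include the DC term."""


class FormatError(DataError):
    """Malformed image stack or metadata."""
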