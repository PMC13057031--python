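"""Exception types shared across the package."""


class MnscoreError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MnscoreError, ValueError):
    """A configuration value violates its documented constraints."""


class PlacementError(MnscoreError, RuntimeError):
    """The simulator could not place the requested number of cells in a field."""


class FieldFormatError(MnscoreError, ValueError):
    """An image or table on disk does not match the expected format."""


class ChannelError(MnscoreError, ValueError):
    """A field is missing the channel an operation requires."""


class UndefinedFrequencyError(MnscoreError, ZeroDivisionError):
    """A frequency was requested with a zero denominator."""
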