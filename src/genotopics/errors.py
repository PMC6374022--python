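"""Exception types shared across the package."""


class GenotopicsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GenotopicsError, ValueError):
    """A configuration value violates its documented constraint."""


class FormatError(GenotopicsError, ValueError):
    """An input file does not match the expected on-disk format."""


class DegenerateInputError(GenotopicsError, ValueError):
    """Input is structurally valid but carries no usable information."""


class AlignmentError(GenotopicsError, ValueError):
    """Individual identifiers cannot be aligned across inputs."""
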