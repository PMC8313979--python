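"""Exception hierarchy shared across the package."""


class GlycoregError(Exception):
    """Base class for all glycoreg errors."""


class ConfigurationError(GlycoregError):
    """A dialect mapping, column name or generator configuration is wrong."""


class ValidationError(GlycoregError):
    """Input data violate a documented invariant (range, duplicate, emptiness)."""


class FormatError(GlycoregError):
    """A file does not conform to the expected on-disk format."""


class DomainError(GlycoregError):
    """Arguments to a computation are inconsistent (margins, partitions, mixed cancers)."""
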