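"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file or string does not conform to the expected format."""


class ConfigurationError(ValueError):
    """Required auxiliary information (mappings, lengths, sizes) is missing."""


class DegeneratePairError(ValueError):
    """A sequence pair has no comparable (gap-free in both) columns."""
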