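"""Exception hierarchy shared by all sproutnet modules."""


class SproutNetError(Exception):
    """Base class for all errors raised by sproutnet."""


class FormatError(SproutNetError):
    """A file on disk does not conform to the expected external format."""


class ConfigurationError(SproutNetError):
    """A parameter or run configuration is outside its documented domain."""


class ContractError(SproutNetError):
    """A precondition of an operation was violated by its inputs."""


class SizeFactorError(SproutNetError):
    """Median-of-ratios normalization is undefined for this matrix
    (no feature has strictly positive counts in every sample)."""
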