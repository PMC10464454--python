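"""Exception hierarchy."""


class PlastophyloError(Exception):
    """Base class for all package errors."""


class FormatError(PlastophyloError):
    """A file did not conform to its expected format."""


class ConfigError(PlastophyloError):
    """Invalid run configuration."""


class TreeError(PlastophyloError):
    """A gene tree or phylogeny violated an expectation."""
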