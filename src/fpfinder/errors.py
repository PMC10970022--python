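"""Exception hierarchy shared across the package."""


class FPFinderError(Exception):
    """Base class for all errors raised by this package."""


class VcfFormatError(FPFinderError):
    """The VCF is unreadable or lacks required fields (e.g. GT)."""


class ManifestError(FPFinderError):
    """The sample manifest is inconsistent with the data it describes."""


class MatrixFormatError(FPFinderError):
    """A presence/absence table file is malformed."""


class ConfigError(FPFinderError):
    """A scoring or simulation configuration is invalid."""


class GeneModelError(FPFinderError):
    """A gene model violates structural constraints (e.g. UTR outside exons)."""
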