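"""Exception hierarchy shared across the package."""


class TspecError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TspecError):
    """A tabular input violates the expected file format (duplicates, bad header)."""


class MetadataError(TspecError):
    """Sample metadata is inconsistent with the expression matrix."""


class ConsistencyError(TspecError):
    """Two inputs that must share a gene/sample space do not."""


class ConfigError(TspecError):
    """A parameter set is invalid or infeasible."""
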