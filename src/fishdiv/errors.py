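"""Exception hierarchy shared by all fishdiv modules."""


class FishdivError(Exception):
    """Base class for all package errors."""


class FormatError(FishdivError):
    """A file is structurally malformed (missing column, non-binary cell...)."""


class ValidationError(FishdivError):
    """Content violates a domain invariant (duplicate id, rank inconsistency...)."""


class ConfigError(FishdivError):
    """A configuration is internally inconsistent or infeasible."""
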