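"""Exception hierarchy for the mSig pipeline."""


class MsigError(Exception):
    """Base class for all pipeline errors."""


class IdentifierError(MsigError):
    """Duplicate or unknown gene/sample identifiers."""


class FormatError(MsigError):
    """Malformed on-disk artifact (ragged rows, bad schema version, ...)."""


class ConfigError(MsigError):
    """Infeasible or inconsistent configuration."""


class CoverageError(MsigError):
    """Too few model genes available in the expression matrix."""


class JoinError(MsigError):
    """Sample identifiers fail to match across joined tables."""


class FitError(MsigError):
    """Model fit failed to converge."""
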