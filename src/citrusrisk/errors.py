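"""Exception hierarchy shared across the package."""


class CitrusRiskError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CitrusRiskError):
    """An input file lacks a required column or has an unusable layout."""


class ValidationError(CitrusRiskError):
    """A value violates a domain invariant (negative concentration, bad counts...)."""


class ReferenceLookupError(CitrusRiskError):
    """A pesticide/commodity pair has no entry in the reference table (strict policy)."""


class ConfigurationError(CitrusRiskError):
    """A scenario or score-table configuration is incomplete or inconsistent."""


class UndefinedRatioError(CitrusRiskError):
    """A frequency or percentage is requested over an empty sample set."""
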