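"""Exception hierarchy shared across the package."""


class ChronovalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ChronovalError):
    """Invalid parameterisation detected before any computation runs."""


class DataError(ChronovalError):
    """Input data violate a structural precondition (missing cells, bad labels)."""


class AnalysisError(ChronovalError):
    """An analysis cannot be carried out on otherwise well-formed data."""
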