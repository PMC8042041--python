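"""Exception hierarchy for mrkit."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A required column, path or parameter is missing or malformed."""


class FormatError(MRKitError):
    """An input file is structurally unusable (e.g. mostly non-numeric)."""


class HarmonizationError(MRKitError):
    """Exposure and outcome tables cannot be merged/aligned."""


class EstimationError(MRKitError):
    """An estimator received degenerate or insufficient instruments."""


class ParameterError(MRKitError):
    """A numeric argument is outside its valid domain."""
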