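"""Exception hierarchy shared across the pipeline."""


class HsGwasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HsGwasError):
    """Invalid configuration values (non-positive counts, empty ranges, ...)."""


class DomainError(HsGwasError):
    """An argument lies outside the mathematical domain of an operation."""


class MissingDataError(HsGwasError):
    """Required observations are absent (empty day, uncovered week, ...)."""


class DegenerateInputError(HsGwasError):
    """Structurally valid input on which the operation is undefined
    (all markers monomorphic, empty QC result, zero total variance)."""


class SimulationError(HsGwasError):
    """The generative model cannot be realized (e.g. non-PSD relationship matrix)."""


class ParseError(HsGwasError):
    """A file does not conform to its expected format; message names the location."""


class DesignError(HsGwasError):
    """The fixed-effect design is singular or otherwise unusable."""
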