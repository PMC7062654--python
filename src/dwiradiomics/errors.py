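"""Exception hierarchy shared across the package."""


class DwiRadiomicsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DwiRadiomicsError):
    """An input file could not be parsed in any supported format."""


class AmbiguityError(FormatError):
    """A multi-slice volume was given without a slice index."""


class CongruenceError(DwiRadiomicsError):
    """A mask does not share its image's pixel grid."""


class InvalidRoiError(DwiRadiomicsError):
    """A region of interest violates the minimum-size or connectivity rules."""


class SchemaError(DwiRadiomicsError):
    """A table or manifest violates its schema (e.g. duplicate feature names)."""


class ContractViolationError(DwiRadiomicsError):
    """An internal numerical contract was broken (e.g. unnormalized GLCM)."""


class UnknownFeatureError(DwiRadiomicsError):
    """A feature name is not in the published catalogue."""


class TaskError(DwiRadiomicsError):
    """A classification/selection task is ill-posed (e.g. a single class)."""


class ConfigError(DwiRadiomicsError):
    """An inconsistent configuration (e.g. even k for k-NN)."""
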