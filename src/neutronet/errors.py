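"""Exception hierarchy shared by all neutronet modules."""


class NeutronetError(Exception):
    """Base class for all neutronet-specific errors."""


class ParseError(NeutronetError):
    """A file does not conform to its expected dialect."""


class DuplicateIdentifierError(NeutronetError):
    """A feature, sample or set identifier occurs more than once."""


class EmptyInputError(NeutronetError):
    """An input file contains no usable records."""


class ConfigError(NeutronetError):
    """A simulation configuration is internally inconsistent."""


class DesignError(NeutronetError):
    """A sample design does not support the requested analysis."""


class SetCoverageError(NeutronetError):
    """A gene set has no usable overlap with the expression matrix."""


class ValidationError(NeutronetError):
    """An in-memory object violates a structural invariant."""


class InsufficientPairsError(NeutronetError):
    """Too few paired observations for a paired test."""
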