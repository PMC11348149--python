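"""Exception hierarchy used across the package."""


class AopmoaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AopmoaError):
    """An input file does not conform to the declared format."""


class ValidationError(AopmoaError):
    """An in-memory object violates a structural invariant."""


class ParameterError(AopmoaError, ValueError):
    """A caller-supplied parameter is out of range or inconsistent."""


class LookupError_(AopmoaError, KeyError):
    """An identifier is not present in the queried structure."""


class InsufficientReplicationError(AopmoaError):
    """A condition has fewer replicates than the operation requires."""


class DegeneratePairError(AopmoaError):
    """A gene pair has a singular pooled covariance and cannot be tested."""


class FitError(AopmoaError):
    """A model fit failed (e.g. singular design)."""


class ComparabilityError(AopmoaError):
    """Two objects built against different references cannot be compared."""
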