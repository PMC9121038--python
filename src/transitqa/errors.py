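"""Exception hierarchy for transitqa."""


class TransitQAError(Exception):
    """Base class for all transitqa errors."""


class InvalidArgumentError(TransitQAError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateTraceError(TransitQAError):
    """A breathing trace has no usable cyclic structure (constant signal, <2 peaks)."""


class EmptyGateError(TransitQAError):
    """A gating window selects no samples of the breathing trace (zero dwell time)."""


class BoundsError(TransitQAError):
    """A phantom (over its motion range) does not fit inside the density grid."""


class GeometryError(TransitQAError):
    """Two images that must share beam geometry do not."""


class NormalizationError(TransitQAError):
    """The reference image has no positive dose to normalise against."""


class UndefinedGPRError(TransitQAError):
    """No evaluable pixels above the dose threshold; passing rate is undefined."""


class FormatError(TransitQAError):
    """An on-disk file does not match the expected layout or its sidecar metadata."""
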