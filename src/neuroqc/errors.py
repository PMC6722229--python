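"""Exception hierarchy for quality-control failures."""


class QCError(Exception):
    """Base class for all package errors."""


class ValidationError(QCError):
    """Input data violates a structural invariant (shape, finiteness, metadata)."""


class DegenerateInputError(QCError):
    """Input is valid but degenerate for the requested operation (e.g. constant image)."""


class SegmentationError(QCError):
    """Brain extraction or tissue segmentation produced an unusable result."""


class GradientSchemeError(ValidationError):
    """Gradient table inconsistent with the series or physically invalid."""
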