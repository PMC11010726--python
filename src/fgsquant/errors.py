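"""Exception hierarchy shared across the pipeline stages."""


class FgsQuantError(Exception):
    """Base class for all fgsquant errors."""


class ParameterError(FgsQuantError, ValueError):
    """An argument or spec field violates its stated domain."""


class GeometryError(FgsQuantError, ValueError):
    """A mask/ellipse violates a geometric precondition (midline, bounds)."""


class SegmentationError(FgsQuantError, RuntimeError):
    """No usable tumor component could be extracted from the image."""


class TransferError(FgsQuantError, RuntimeError):
    """Too many mask pixels would be lost when transferring between images."""


class MaskError(FgsQuantError, ValueError):
    """Masks overlap, are empty, or do not match the image shape."""


class QuantificationError(FgsQuantError, RuntimeError):
    """A ratio could not be formed (non-positive reference mean)."""


class InputError(FgsQuantError, ValueError):
    """Tabular input is malformed (missing pair, bad weight, too few values)."""


class NoSeparationError(FgsQuantError, ValueError):
    """Tumor and normal median colors coincide; no projection direction exists."""


class AggregationError(FgsQuantError, ValueError):
    """Projection vectors cancel; their mean has no direction."""


class DegenerateDataError(FgsQuantError, ValueError):
    """A statistical test received data with no usable variation."""


class PipelineIOError(FgsQuantError, OSError):
    """A file could not be read/written or its metadata is inconsistent."""
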