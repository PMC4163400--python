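"""Exception hierarchy for the explant-analysis pipeline.

Every stage raises a subclass of :class:`PipelineError` so the CLI can
name the failing stage and exit non-zero without a traceback.
"""


class PipelineError(Exception):
    """Base class for all pipeline failures."""


class InvalidInputError(PipelineError, ValueError):
    """Input image/mask violates a precondition (shape, emptiness, range)."""


class InvalidParameterError(PipelineError, ValueError):
    """A numeric parameter is outside its valid domain."""


class DegenerateHistogramError(PipelineError):
    """Entropy threshold requested on a single-intensity histogram."""


class SegmentationFailureError(PipelineError):
    """Thresholding produced no usable foreground object."""


class RayOriginError(PipelineError):
    """Mask centroid falls outside the foreground; ray casting undefined."""


class MissingIntersectionError(PipelineError):
    """A cast ray never crossed the object contour."""


class OverSmoothingError(PipelineError):
    """Contour smoothing annihilated the foreground component."""


class InvalidMergeError(PipelineError):
    """Merge gain requested for a non-adjacent region/cluster pair."""


class ConstraintError(PipelineError, ValueError):
    """Phantom specification is internally infeasible."""


class UndefinedScoreError(PipelineError):
    """Similarity score undefined (e.g. Dice of two empty masks)."""
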