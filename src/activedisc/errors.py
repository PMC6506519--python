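"""Exception hierarchy shared across the package."""


class ActiveDiscError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ActiveDiscError, ValueError):
    """An argument violates a documented precondition."""


class InvalidGeometryError(InvalidArgumentError):
    """Circle pair does not satisfy the required containment geometry."""


class DegenerateTemplateError(InvalidArgumentError):
    """Active-disc template collapsed below the pixel scale."""


class DegenerateHistogramError(ActiveDiscError):
    """Histogram has too few distinct intensity levels for the requested split."""


class NoCupFoundError(ActiveDiscError):
    """Coarse cup extraction produced no usable candidate region."""


class ChannelMissingError(InvalidArgumentError):
    """Input image lacks the color channels the pipeline requires."""


class AmbiguousLocalizationError(ActiveDiscError):
    """Correlation surface has no unique peak (e.g. a flat image).

    ``tied_positions`` holds up to ``max_listed`` (x, y) positions, in
    full-resolution coordinates, that share the maximal score.
    """

    def __init__(self, message, tied_positions=()):
        super().__init__(message)
        self.tied_positions = list(tied_positions)


class FitFailureError(ActiveDiscError):
    """Active-disc optimization diverged or had no contrast to work with.

    ``trace`` carries the energy values visited before failure, for debugging.
    """

    def __init__(self, message, trace=()):
        super().__init__(message)
        self.trace = list(trace)


class PipelineError(ActiveDiscError):
    """A stage of the end-to-end grading pipeline failed.

    Attributes
    ----------
    stage : str
        Name of the failing stage (``localization``, ``disc_segmentation``,
        ``cup_segmentation``, ``clinical_geometry`` or ``grading``).
    partial : dict
        Results of the stages that completed before the failure.
    """

    def __init__(self, stage, cause, partial=None):
        super().__init__(f"pipeline failed at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = dict(partial or {})
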