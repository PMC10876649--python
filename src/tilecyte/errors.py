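"""Exception hierarchy for the tilecyte pipeline."""


class TilecyteError(Exception):
    """Base class for all tilecyte errors."""


class EmptyROIError(TilecyteError):
    """Raised when an operation requires at least one ROI pixel."""


class NoNucleiError(TilecyteError):
    """Raised when an operation requires at least one nucleus."""


class CentroidOutsideROIError(TilecyteError):
    """Raised when a nucleus centroid falls on a background pixel."""


class PlacementInfeasibleError(TilecyteError):
    """Raised when the hard-core sampler cannot place the requested nuclei.

    Carries the number of nuclei actually placed in ``achieved``.
    """

    def __init__(self, requested: int, achieved: int, attempts: int):
        self.requested = requested
        self.achieved = achieved
        self.attempts = attempts
        super().__init__(
            f"placement infeasible: placed {achieved} of {requested} nuclei "
            f"after {attempts} attempts"
        )


class UnknownCellTypeError(TilecyteError):
    """Raised when a ground-truth table names a cell type absent from the config."""


class NotNormalizedError(TilecyteError):
    """Raised when tile aggregation receives an unnormalized channel."""


class PipelineStageError(TilecyteError):
    """Wraps a failure inside a pipeline stage, naming stage and sample."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        self.stage = stage
        self.sample_id = sample_id
        self.__cause__ = cause
        super().__init__(f"stage '{stage}' failed for sample '{sample_id}': {cause}")
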