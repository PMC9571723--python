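"""Exception hierarchy for the aquacolor pipeline.

Every stage raises a subclass of :class:`AquacolorError` so the pipeline
orchestrator can tag failures with the stage that produced them.
"""


class AquacolorError(Exception):
    """Base class for all aquacolor errors."""


class DomainError(AquacolorError, ValueError):
    """An input value lies outside the operation's documented domain."""


class LocalizationError(AquacolorError):
    """The checkerboard could not be localized in the image."""


class ExtractionError(AquacolorError):
    """Block-color extraction from the normalized ROI failed."""


class EstimationError(AquacolorError):
    """The correction-matrix least-squares system could not be solved."""


class MaskError(AquacolorError, ValueError):
    """A segmentation mask failed validation."""


class CandidateExhaustedError(AquacolorError):
    """Candidate sampling hit the attempt cap before collecting N patches."""

    def __init__(self, message: str, attempts: int, best_q: float):
        super().__init__(message)
        self.attempts = attempts
        self.best_q = best_q


class SceneSpecError(AquacolorError, ValueError):
    """A synthetic scene specification is geometrically inconsistent."""
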