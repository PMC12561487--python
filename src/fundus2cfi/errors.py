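"""Exception types shared across the pipeline."""


class Fundus2CFIError(Exception):
    """Base class for package errors."""


class ODDetectionError(Fundus2CFIError):
    """The optic-disc detector returned zero detections."""


class InsufficientMatchesError(Fundus2CFIError):
    """Fewer than four keypoint correspondences survived matching."""


class DegenerateGeometryError(Fundus2CFIError):
    """Homography estimation or warping hit a degenerate configuration."""


class RegistrationStageError(Fundus2CFIError):
    """A registration sub-stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"registration failed at stage {stage!r}: {cause}")
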