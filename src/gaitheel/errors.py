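"""Exception hierarchy shared across the package."""


class GaitHeelError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GaitHeelError, ValueError):
    """A parameter object violates its invariants."""


class InsufficientCorrespondencesError(GaitHeelError, ValueError):
    """Fewer than four image/floor point pairs were supplied."""


class DegenerateConfigurationError(GaitHeelError, ValueError):
    """Point configuration is rank-deficient (e.g. collinear floor marks)."""


class PointAtInfinityError(GaitHeelError, ValueError):
    """Projection sent a point to (numerical) infinity."""


class PoseParseError(GaitHeelError, ValueError):
    """Malformed pose JSON; the message names the offending frame."""


class PoseDialectError(GaitHeelError, ValueError):
    """Pose JSON does not follow the 25-keypoint dialect."""


class MissingKeypointError(GaitHeelError, ValueError):
    """A required keypoint has confidence zero (undetected)."""


class FrameTooSmallError(GaitHeelError, ValueError):
    """Source video frame is smaller than the fixed crop size."""


class EmptyOverlapError(GaitHeelError, ValueError):
    """Two trajectories share no common frames."""


class SeriesTooShortError(GaitHeelError, ValueError):
    """Distance series shorter than the smoothing window."""


class InvalidSplitError(GaitHeelError, ValueError):
    """Subject split counts inconsistent with the available subjects."""


class InvalidSpecError(GaitHeelError, ValueError):
    """Unknown backbone/head or otherwise invalid model specification."""


class UndecodableHeatmapError(GaitHeelError, ValueError):
    """Heatmap contains no positive response after clamping."""


class DivergenceError(GaitHeelError, RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
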