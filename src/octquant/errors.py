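"""Exception taxonomy for the OCT analysis pipeline.

Each failure mode the pipeline can hit has a distinct, named exception so
callers (and the CLI) can report which stage failed and why.
"""


class OctQuantError(Exception):
    """Base class for all octquant failures."""


# --- stack loading ---------------------------------------------------------

class StackLoadError(OctQuantError):
    """A b-scan stack could not be loaded."""


class MissingPathError(StackLoadError):
    """The requested stack path does not exist."""


class ZeroFramesError(StackLoadError):
    """The stack location contained no readable frames."""


class FrameShapeMismatchError(StackLoadError):
    """Frames in one stack do not share identical dimensions."""


class UnreadableFrameError(StackLoadError):
    """A frame file exists but could not be decoded."""


class ChannelCountError(OctQuantError):
    """Frame channel count is neither 1 nor 3."""


# --- segmentation ----------------------------------------------------------

class SegmentationError(OctQuantError):
    """Base class for layer-segmentation failures."""


class NoRetinalBandError(SegmentationError):
    """No column of the b-scan contains a sustained bright band."""


class OrderingViolationError(SegmentationError):
    """Boundary depth ordering could not be enforced after smoothing."""


class BScanRejectedError(SegmentationError):
    """Too many columns failed detection; the b-scan is unusable."""


class GeometryMismatchError(OctQuantError):
    """Boundaries, masks or aggregates do not match the grid geometry."""


# --- region statistics -----------------------------------------------------

class EmptyRegionError(OctQuantError):
    """A region mask selects no pixels."""


class ZeroRPESignalError(OctQuantError):
    """Mean RPE intensity is zero; the VIT/RPE ratio is undefined."""


# --- statistics ------------------------------------------------------------

class DegenerateInputError(OctQuantError):
    """Statistical input is degenerate (constant sample, no nonzero
    differences, too few points, zero variance in x, ...)."""


# --- synthetic generation --------------------------------------------------

class DesignError(OctQuantError):
    """Invalid phantom parameters or study design."""
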