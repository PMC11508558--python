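"""Exception hierarchy shared across the package."""


class HSFocusError(Exception):
    """Base class for all package-specific errors."""


class StackLoadError(HSFocusError, ValueError):
    """A stack on disk could not be loaded."""


class MissingHeaderError(StackLoadError):
    """ENVI raw file without its companion header."""


class FrameShapeError(StackLoadError):
    """Frames in one stack do not share a common shape."""


class NonMonotonicZError(StackLoadError):
    """Focal positions are not strictly increasing."""


class ROIError(HSFocusError, ValueError):
    """Region of interest falls outside the frame."""


class DegenerateFrameError(HSFocusError, ValueError):
    """A frame is constant (or otherwise degenerate) where variation is required."""


class FlatCurveError(HSFocusError, ValueError):
    """A focus curve with no variation cannot be normalized or ranked."""
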