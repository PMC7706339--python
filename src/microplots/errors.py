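"""Exception types raised across the pipeline stages."""


class MicroplotsError(Exception):
    """Base class for all package-specific failures."""


class UnsegmentableImageError(MicroplotsError):
    """The vegetation-index map is constant; no threshold can split it."""


class DetectionError(MicroplotsError):
    """Column/row detection could not reconcile intervals with the layout."""


class NotVisibleError(MicroplotsError):
    """A world point projects behind the camera (depth <= 0)."""


class FrameMismatchError(MicroplotsError):
    """No plot is visible in any camera; inputs likely use different frames."""


class RasterFormatError(MicroplotsError):
    """Unreadable raster or unsupported band layout."""
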