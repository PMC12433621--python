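"""Exception hierarchy for the btd package."""


class BTDError(Exception):
    """Base class for all btd-specific errors."""


class ImageReadError(BTDError):
    """The input file could not be read or decoded to a single channel."""


class ImageRangeError(BTDError):
    """Pixel values fall outside the [0, 1] range required for output."""


class ShapeMismatchError(BTDError):
    """Two rasters that must share a grid have different shapes."""


class EmptyMaskError(BTDError):
    """The bone mask contains no pixels (no bone-like region found)."""


class NoBoneSignalError(BTDError):
    """f and T agree everywhere: the image carries no bone component."""


class DegeneratePixelError(BTDError):
    """The scaled bone term B/alpha reaches 1 somewhere, so the
    tissue-from-bone denominator vanishes."""

    def __init__(self, positions):
        self.positions = positions
        head = ", ".join(str(tuple(p)) for p in positions[:5])
        more = "" if len(positions) <= 5 else f" (+{len(positions) - 5} more)"
        super().__init__(f"B/alpha >= 1 - eps at pixels: {head}{more}")


class PhantomPlacementError(BTDError):
    """Random ellipse placement failed; the phantom spec is too crowded."""
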