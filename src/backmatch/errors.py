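"""Exception hierarchy for the backmatch pipeline."""


class BackmatchError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(BackmatchError):
    """A synthetic scene specification violates its invariants."""


class ImageIOError(BackmatchError):
    """An input image could not be read or has the wrong layout."""


class SingleChannelError(ImageIOError):
    """Input is already grayscale; skip the green-channel extraction."""


class ParameterError(BackmatchError):
    """A filter or analysis parameter is out of its valid range."""


class ProvenanceError(BackmatchError):
    """A grayscale scene was not produced by the sanctioned preprocessing chain."""


class ShapeError(BackmatchError):
    """A patch or raster has the wrong shape (e.g. non-square FFT patch)."""


class BoundsError(BackmatchError):
    """A requested patch or window does not lie fully inside the image."""


class MantleSizeError(BackmatchError):
    """The mantle reference patch is smaller than the minimum allowed side."""


class DegenerateProfileError(BackmatchError):
    """All radial bins were dropped; no spectral profile remains."""


class InsufficientDataError(BackmatchError):
    """Fewer than three positive-power bins; log-log regression undefined."""


class UndefinedReferenceError(BackmatchError):
    """The reference statistic is zero; relative similarity is undefined."""


class RegionSizeError(BackmatchError):
    """A labelled region cannot contain a single sampling square."""

    def __init__(self, label: str, side: int):
        self.label = label
        self.side = side
        super().__init__(
            f"region {label!r} cannot contain a single {side}x{side} px square"
        )


class ConfigError(BackmatchError):
    """A workflow configuration failed validation."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field {field!r}: {message}")
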