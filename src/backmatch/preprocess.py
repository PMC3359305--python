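"""Preprocessing chain: green channel -> Gaussian denoise -> top-hat.

The spectral analysis operates on a single-channel raster obtained in a
fixed order: the green plane of the RGB photograph (the channel closest to
the spectral sensitivity of a cephalopod's single visual pigment, and the
least noisy channel of underwater photographs), a small Gaussian filter
against high-frequency sensor noise, and a white top-hat (disk structuring
element, radius 25 px) against uneven illumination.  Downstream stages
refuse a :class:`GrayScene` whose provenance differs from this chain,
because the spectral statistics are only comparable between patches that
received identical filtering.

The Gaussian is parameterised the MATLAB way: ``delta`` is the kernel size
in pixels (default 2, the protocol value) and ``sigma`` is the standard
deviation (default 0.5 px, MATLAB's ``fspecial('gaussian', hsize)``
default).  Reading the protocol's bare "2" as sigma instead would attenuate
the window-Nyquist power by ~17 decades and erase the very spectral-slope
differences the method measures; see docs/methods.md for the measurement.

Both filters use reflective boundary handling so that no dark border is
injected into windowed spectra near the image edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, white_tophat

from .errors import (
    ImageIOError,
    ParameterError,
    ProvenanceError,
    SingleChannelError,
)

__all__ = [
    "GrayScene",
    "load_rgb",
    "green_channel",
    "gaussian_smooth",
    "tophat_correct",
    "preprocess",
    "preprocess_gray",
    "check_provenance",
    "DEFAULT_GAUSSIAN_DELTA",
    "DEFAULT_SIGMA",
    "DEFAULT_SE_RADIUS",
]

#: protocol Gaussian parameter: kernel size in px (MATLAB fspecial hsize)
DEFAULT_GAUSSIAN_DELTA = 2.0
#: Gaussian standard deviation in px (MATLAB fspecial default for a bare hsize)
DEFAULT_SIGMA = 0.5
DEFAULT_SE_RADIUS = 25

#: the only sanctioned preprocessing chains (first step depends on input kind)
_SANCTIONED_FIRST = ("green_channel", "grayscale_input")
_SANCTIONED_REST = ("gaussian", "tophat")


@dataclass
class GrayScene:
    """Single-channel scene in [0, 1] with a record of applied filters."""

    pixels: np.ndarray
    provenance: list[tuple[str, dict]] = field(default_factory=list)
    source_path: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ImageIOError("GrayScene requires a 2-D raster")
        if not np.all(np.isfinite(self.pixels)):
            raise ImageIOError("GrayScene pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_step(self, pixels: np.ndarray, step: str, **params) -> "GrayScene":
        return GrayScene(
            pixels=pixels,
            provenance=[*self.provenance, (step, params)],
            source_path=self.source_path,
        )


def load_rgb(path) -> np.ndarray:
    """Load an image file as an (H, W, 3) uint8/uint16 array in R,G,B order.

    Palette/CMYK/RGBA images are converted to RGB.  A single-channel file
    raises :class:`SingleChannelError` telling the caller to skip the
    green-channel step and use :func:`preprocess_gray` instead.
    """
    from PIL import Image, UnidentifiedImageError

    try:
        img = Image.open(path)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if img.mode in ("L", "I", "I;16", "F", "1"):
        raise SingleChannelError(
            f"{path} is single-channel; skip green extraction (use preprocess_gray)"
        )
    if img.mode != "RGB":
        img = img.convert("RGB")
    return np.asarray(img)


def green_channel(rgb: np.ndarray, source_path: str | None = None) -> GrayScene:
    """Extract the G plane and rescale it to [0, 1]."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ImageIOError("green_channel expects an (H, W, 3) raster")
    g = rgb[..., 1].astype(float)
    if np.issubdtype(rgb.dtype, np.integer):
        g = g / float(np.iinfo(rgb.dtype).max)
    return GrayScene(g, provenance=[("green_channel", {})], source_path=source_path)


def gaussian_smooth(
    img: GrayScene,
    sigma: float = DEFAULT_SIGMA,
    delta: float = DEFAULT_GAUSSIAN_DELTA,
) -> GrayScene:
    """Linear Gaussian convolution (reflective boundary).

    ``sigma`` is the standard deviation in px; ``delta`` is the nominal
    kernel size in px and only bounds the truncation radius (never below
    one pixel), mirroring MATLAB's (hsize, sigma) parameter pair.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if delta <= 0:
        raise ParameterError("delta (kernel size) must be > 0")
    truncate = max(delta / 2.0, 1.0) / sigma
    out = ndi.gaussian_filter(img.pixels, sigma=sigma, mode="reflect",
                              truncate=truncate)
    return img.with_step(out, "gaussian", sigma=sigma, delta=delta)


def tophat_correct(img: GrayScene, se_radius: int = DEFAULT_SE_RADIUS) -> GrayScene:
    """White top-hat: image minus its morphological opening by a disk.

    Removes image structure larger than the structuring element — in
    practice the smooth illumination component — while retaining texture at
    scales below the SE radius.  Output is non-negative.
    """
    if se_radius < 1:
        raise ParameterError("se_radius must be >= 1")
    if se_radius > min(img.shape) / 2:
        warnings.warn(
            "top-hat SE radius exceeds half the image side; the filter degenerates",
            stacklevel=2,
        )
    out = white_tophat(img.pixels, footprint=disk(se_radius))
    out = np.clip(out, 0.0, None)  # guard fp residue; opening <= image
    return img.with_step(out, "tophat", se_radius=se_radius)


def preprocess(
    rgb: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    se_radius: int = DEFAULT_SE_RADIUS,
    delta: float = DEFAULT_GAUSSIAN_DELTA,
    source_path: str | None = None,
) -> GrayScene:
    """Full sanctioned chain on an RGB raster: green -> Gaussian -> top-hat."""
    return tophat_correct(
        gaussian_smooth(green_channel(rgb, source_path), sigma, delta), se_radius
    )


def preprocess_gray(
    gray: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    se_radius: int = DEFAULT_SE_RADIUS,
    delta: float = DEFAULT_GAUSSIAN_DELTA,
    source_path: str | None = None,
) -> GrayScene:
    """Sanctioned chain for an already single-channel scene (e.g. a
    synthetic rendering): the green-extraction step is replaced by a
    recorded ``grayscale_input`` step."""
    gs = GrayScene(
        np.asarray(gray, dtype=float),
        provenance=[("grayscale_input", {})],
        source_path=source_path,
    )
    return tophat_correct(gaussian_smooth(gs, sigma, delta), se_radius)


def check_provenance(scene: GrayScene) -> None:
    """Refuse scenes not produced by the sanctioned chain, in order."""
    steps = [s for s, _ in scene.provenance]
    if (
        len(steps) != 3
        or steps[0] not in _SANCTIONED_FIRST
        or tuple(steps[1:]) != _SANCTIONED_REST
    ):
        raise ProvenanceError(
            "spectral analysis requires the preprocessing chain "
            f"{_SANCTIONED_FIRST[0]}|{_SANCTIONED_FIRST[1]} -> gaussian -> tophat; "
            f"got {steps!r}"
        )
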