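"""Rotationally averaged 2D power spectra and their log-log statistics.

The texture descriptor at the core of the pipeline: a square patch is
mean-subtracted and Fourier transformed; the 2-D power spectrum is averaged
over annuli of (integer-rounded) radial spatial frequency; and an ordinary
least-squares line is fitted to log10(power) against log10(frequency).  The
triple (RA-mean, RA-slope, RA-intercept) summarises the patch's texture
irrespective of orientation: natural textures follow ``P(f) ~ f**(-beta)``,
so the slope estimates ``-beta``.

Conventions (fixed here, used everywhere):

* Power is normalised so that its sum equals the sum of squared deviations
  of the patch (Parseval); the DC bin is exactly zero after mean
  subtraction.
* The profile is truncated at the Nyquist radius ``floor(side / 2)``; the
  DC bin and bins with radius below ``drop_low`` (default 2%) of the
  Nyquist radius are excluded to avoid low-frequency spiking.
* Logarithms are base 10.  The slope is base-invariant; RA-mean and the
  intercept are base-dependent and reported as log10 quantities.
* RA-mean is the arithmetic mean of log10(power) over the retained bins.
* No window taper is applied before the FFT (``taper="hann"`` is available
  for sensitivity checks, default off).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import (
    BoundsError,
    DegenerateProfileError,
    InsufficientDataError,
    MantleSizeError,
    ShapeError,
)
from .preprocess import GrayScene, check_provenance

__all__ = [
    "SpectralProfile",
    "RAStats",
    "power_spectrum_2d",
    "rotational_average",
    "loglog_regression",
    "ra_stats",
    "DEFAULT_DROP_LOW",
    "MIN_MANTLE_SIDE",
]

DEFAULT_DROP_LOW = 0.02
MIN_MANTLE_SIDE = 150
MIN_PATCH_SIDE = 16


@dataclass(frozen=True)
class SpectralProfile:
    """Radial profile of a 2-D power spectrum.

    ``radial_freq`` is in cycles per patch side (integer annulus radii),
    strictly increasing; ``mean_power`` is the mean 2-D power over each
    annulus.  Bins excluded by the low-frequency rule are absent.
    """

    radial_freq: np.ndarray
    mean_power: np.ndarray
    n_bins: int
    dropped_low_fraction: float

    def __post_init__(self):
        if np.any(np.diff(self.radial_freq) <= 0):
            raise DegenerateProfileError("radial_freq must be strictly increasing")


@dataclass(frozen=True)
class RAStats:
    """Log-log regression statistics of one patch's radial spectrum.

    ``ra_mean`` is the mean of log10(mean annulus power) over retained
    bins; ``slope``/``intercept`` are the OLS fit of log10(power) on
    log10(frequency); ``ks_p`` is the one-sample Kolmogorov–Smirnov
    p-value of the retained log-power sample against a normal with the
    sample's own mean and SD (reported, never used as a gate).
    """

    ra_mean: float
    slope: float
    intercept: float
    r2: float
    ks_p: float
    patch_origin: tuple[int, int]
    patch_side: int
    log_power: np.ndarray  # retained log10 annulus powers (the KS/gate sample)
    log_freq: np.ndarray
    n_zero_bins_dropped: int = 0

    @property
    def ra_mean_linear(self) -> float:
        """RA-mean mapped back to the linear power domain (10**ra_mean)."""
        return float(10.0 ** self.ra_mean)


def power_spectrum_2d(patch: np.ndarray) -> np.ndarray:
    """Centered 2-D power spectrum of a mean-subtracted square patch.

    Normalised so that ``power.sum()`` equals the sum of squared
    deviations of the patch from its mean (Parseval); the DC bin (at the
    center after ``fftshift``) is zero.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ShapeError(f"patch must be square 2-D, got {patch.shape}")
    side = patch.shape[0]
    if side < MIN_PATCH_SIDE:
        raise ShapeError(f"patch side {side} < minimum {MIN_PATCH_SIDE}")
    if not np.all(np.isfinite(patch)):
        raise ShapeError("patch values must be finite")
    centred = patch - patch.mean()
    spectrum = np.fft.fftshift(np.fft.fft2(centred))
    return (spectrum.real**2 + spectrum.imag**2) / (side * side)


class _RadialBinner:
    """Precomputed annulus geometry for one (side, drop_low) combination.

    Pixels are binned by their radial distance from the spectrum center
    (the DC position after fftshift, index ``side // 2``), rounded to the
    nearest integer.  Retained radii are ``1 .. floor(side/2)`` excluding
    radii strictly below ``drop_low * floor(side/2)``.
    """

    def __init__(self, side: int, drop_low: float):
        if not (0 <= drop_low < 0.5):
            raise DegenerateProfileError("drop_low must be in [0, 0.5)")
        c = side // 2
        yy, xx = np.ogrid[:side, :side]
        r = np.rint(np.hypot(yy - c, xx - c)).astype(np.intp)
        self.side = side
        self.flat_radius = r.ravel()
        self.counts = np.bincount(self.flat_radius)
        self.max_radius = side // 2
        radii = np.arange(self.counts.size)
        keep = (
            (radii >= 1)
            & (radii <= self.max_radius)
            & (radii >= drop_low * self.max_radius)
            & (self.counts > 0)
        )
        self.kept_radii = radii[keep]
        self.kept_counts = self.counts[keep].astype(float)
        if self.kept_radii.size == 0:
            raise DegenerateProfileError("all radial bins were dropped")
        self.log_freq = np.log10(self.kept_radii.astype(float))

    def bin_means(self, power: np.ndarray) -> np.ndarray:
        sums = np.bincount(
            self.flat_radius, weights=power.ravel(), minlength=self.counts.size
        )
        return sums[self.kept_radii] / self.kept_counts


@lru_cache(maxsize=32)
def _binner(side: int, drop_low: float) -> _RadialBinner:
    return _RadialBinner(side, drop_low)


def rotational_average(
    power: np.ndarray, drop_low: float = DEFAULT_DROP_LOW
) -> SpectralProfile:
    """Rotational average of a centered power spectrum.

    The DC bin is always removed; annuli with radius strictly below
    ``drop_low`` times the Nyquist radius are removed (the stated purpose
    of the low-frequency exclusion is to avoid spiking from near-DC bins);
    the profile is truncated at the Nyquist radius ``floor(side/2)``.
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 2 or power.shape[0] != power.shape[1]:
        raise ShapeError("power raster must be square")
    b = _binner(power.shape[0], float(drop_low))
    return SpectralProfile(
        radial_freq=b.kept_radii.astype(float),
        mean_power=b.bin_means(power),
        n_bins=int(b.kept_radii.size),
        dropped_low_fraction=float(drop_low),
    )


def loglog_regression(
    profile: SpectralProfile,
    patch_origin: tuple[int, int] = (0, 0),
    patch_side: int = 0,
) -> RAStats:
    """OLS fit of log10(mean annulus power) on log10(radial frequency).

    Zero-power bins cannot be logged and are excluded (their count is
    recorded); at least three positive bins are required.
    """
    pos = profile.mean_power > 0
    n_dropped = int(np.count_nonzero(~pos))
    if np.count_nonzero(pos) < 3:
        raise InsufficientDataError(
            f"only {np.count_nonzero(pos)} positive-power bins; need >= 3"
        )
    x = np.log10(profile.radial_freq[pos])
    y = np.log10(profile.mean_power[pos])
    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    sxx = float(dx @ dx)
    slope = float(dx @ (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sst = float(((y - ybar) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float(resid @ resid) / sst
    sd = y.std(ddof=1)
    if sd > 0:
        ks_p = float(stats.kstest(y, "norm", args=(ybar, sd)).pvalue)
    else:
        ks_p = float("nan")
    return RAStats(
        ra_mean=float(ybar),
        slope=slope,
        intercept=float(intercept),
        r2=float(r2),
        ks_p=ks_p,
        patch_origin=tuple(patch_origin),
        patch_side=int(patch_side),
        log_power=y,
        log_freq=x,
        n_zero_bins_dropped=n_dropped,
    )


def _scene_pixels(scene) -> np.ndarray:
    """Accept a GrayScene (provenance-checked) or a plain 2-D array."""
    if isinstance(scene, GrayScene):
        check_provenance(scene)
        return scene.pixels
    return np.asarray(scene, dtype=float)


def ra_stats(
    scene,
    origin: tuple[int, int],
    side: int,
    drop_low: float = DEFAULT_DROP_LOW,
    is_mantle: bool = False,
    min_mantle_side: int = MIN_MANTLE_SIDE,
) -> RAStats:
    """Spectral statistics of the square patch at ``origin`` (top-left).

    A patch designated as the mantle reference must have
    ``side >= min_mantle_side`` (default 150 px, the protocol minimum for
    a usable mantle sample); comparison windows only need ``side >= 16``.
    """
    pixels = _scene_pixels(scene)
    r, c = origin
    if is_mantle and side < min_mantle_side:
        raise MantleSizeError(
            f"mantle patch side {side} < required {min_mantle_side} px"
        )
    if r < 0 or c < 0 or r + side > pixels.shape[0] or c + side > pixels.shape[1]:
        raise BoundsError(
            f"patch origin {origin} side {side} exceeds scene {pixels.shape}"
        )
    power = power_spectrum_2d(pixels[r : r + side, c : c + side])
    profile = rotational_average(power, drop_low=drop_low)
    return loglog_regression(profile, patch_origin=(r, c), patch_side=side)
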