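"""Per-pixel background-matching similarity maps.

A window the size of the mantle reference patch slides over the whole
scene (stride 1 by default); at every position the window's
rotationally-averaged spectral statistics are compared with the mantle's
and the result is assigned to the window's central pixel.  Two numbers are
produced per position:

* a *mean gate*: the window passes when its RA-mean (in the linear power
  domain) is at least 90% similar to the mantle's AND a Mann-Whitney U
  test between the two retained log-power samples is non-significant;
  where the gate fails, no similarity is reported (the pixel is masked,
  never plotted);
* a *slope similarity* in [0, 1]: ``1 - |slope_ref - slope_win| /
  |slope_ref|``, clamped at zero.

The map is undefined inside a border of half the window side (windows
there would leave the image) and inside user-annotated hidden zones (areas
the animal cannot see from its position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import BoundsError, UndefinedReferenceError
from .multipoint import mann_whitney_u
from .regions import RegionSet
from .spectral import (
    DEFAULT_DROP_LOW,
    MIN_MANTLE_SIDE,
    RAStats,
    _binner,
    power_spectrum_2d,
    ra_stats,
)
from . import spectral

__all__ = [
    "GateResult",
    "SimilarityMap",
    "similarity",
    "mean_gate",
    "sliding_map",
    "threshold_overlay",
    "summarize_region",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.90
DEFAULT_GATE_ALPHA = 0.05


def similarity(ref_stat: float, win_stat: float) -> float:
    """Relative-difference similarity: ``max(0, 1 - |ref - win| / |ref|)``.

    Symmetric in sign conventions (absolute values throughout); equals 1
    iff the statistics are equal; undefined for a zero reference.
    """
    if ref_stat == 0:
        raise UndefinedReferenceError("reference statistic is zero")
    return max(0.0, 1.0 - abs(ref_stat - win_stat) / abs(ref_stat))


class GateResult(NamedTuple):
    passed: bool
    mean_similarity: float
    mw_p: float


def mean_gate(
    mantle: RAStats,
    window: RAStats,
    alpha: float = DEFAULT_GATE_ALPHA,
    threshold: float = DEFAULT_THRESHOLD,
    mean_domain: str = "log",
) -> GateResult:
    """The RA-mean gate for one window.

    Passes iff the RA means are at least ``threshold`` similar AND the
    Mann-Whitney U test between the two retained log-power samples is
    non-significant at ``alpha``.  Both sub-conditions are returned so they
    can be logged separately.

    The RA-mean is a statistic of the log-log regression plot, so the
    relative-difference similarity is applied to it directly
    (``mean_domain="log"``).  ``mean_domain="linear"`` compares
    ``10**ra_mean`` instead; that variant is far stricter, because local
    power fluctuations of natural-statistics textures exceed 10% between
    same-texture windows.
    """
    if mean_domain == "log":
        sim = similarity(mantle.ra_mean, window.ra_mean)
    elif mean_domain == "linear":
        sim = similarity(mantle.ra_mean_linear, window.ra_mean_linear)
    else:
        raise ValueError("mean_domain must be 'log' or 'linear'")
    mw = mann_whitney_u(mantle.log_power, window.log_power)
    return GateResult(passed=(sim >= threshold) and (mw.p > alpha),
                      mean_similarity=sim, mw_p=mw.p)


@dataclass
class SimilarityMap:
    """Gated per-pixel similarity rasters plus their masks.

    ``slope_similarity`` is NaN wherever the map is undefined (outside the
    analyzable area, in hidden zones, or where the mean gate failed).
    ``edge_mask`` is True inside the analyzable area, which excludes a
    border of exactly ``floor(window_side / 2)`` px.
    """

    slope_similarity: np.ndarray
    mean_similarity: np.ndarray
    gate_mask: np.ndarray
    edge_mask: np.ndarray
    hidden_mask: np.ndarray
    interpolated: np.ndarray
    threshold: float
    stride: int
    mantle_ref: RAStats
    params: dict = field(default_factory=dict)

    @property
    def analyzable(self) -> np.ndarray:
        return self.edge_mask & self.hidden_mask

    @property
    def defined(self) -> np.ndarray:
        return self.analyzable & self.gate_mask

    @property
    def gate_pass_fraction(self) -> float:
        n = int(self.analyzable.sum())
        return float((self.gate_mask & self.analyzable).sum()) / n if n else float("nan")

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Slope similarity with gate-failed analyzable pixels set to
        ``fill`` (no resemblance) and non-analyzable pixels NaN."""
        out = np.full(self.slope_similarity.shape, np.nan)
        out[self.analyzable] = fill
        d = self.defined & np.isfinite(self.slope_similarity)
        out[d] = self.slope_similarity[d]
        return out


def _window_stats_fast(patch: np.ndarray, binner) -> tuple[float, float, np.ndarray] | None:
    """(slope, ra_mean, log_power) of one window via the cached annulus
    geometry; None when the profile has a non-positive bin (degenerate)."""
    power = power_spectrum_2d(patch)
    means = binner.bin_means(power)
    if np.any(means <= 0):
        return None
    y = np.log10(means)
    x = binner.log_freq
    xbar = x.mean()
    dx = x - xbar
    slope = float(dx @ (y - y.mean())) / float(dx @ dx)
    return slope, float(y.mean()), y


def sliding_map(
    scene,
    mantle_origin: tuple[int, int],
    mantle_side: int,
    stride: int = 1,
    threshold: float = DEFAULT_THRESHOLD,
    hidden_rois: RegionSet | None = None,
    drop_low: float = DEFAULT_DROP_LOW,
    gate_alpha: float = DEFAULT_GATE_ALPHA,
    mean_domain: str = "log",
    min_mantle_side: int = MIN_MANTLE_SIDE,
) -> SimilarityMap:
    """Slide a mantle-sized window over the scene and build the gated map.

    Window statistics are assigned to the central pixel (offset
    ``floor(side/2)`` from the window's top-left).  With ``stride > 1``
    the skipped pixels take the value of the nearest computed position and
    are flagged in ``interpolated``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pixels = spectral._scene_pixels(scene)
    h, w = pixels.shape
    side = mantle_side
    if (
        mantle_origin[0] < 0
        or mantle_origin[1] < 0
        or mantle_origin[0] + side > h
        or mantle_origin[1] + side > w
    ):
        raise BoundsError("mantle window overlaps the image border")
    if mean_domain not in ("log", "linear"):
        raise ValueError("mean_domain must be 'log' or 'linear'")
    mantle = ra_stats(
        pixels, mantle_origin, side, drop_low=drop_low,
        is_mantle=True, min_mantle_side=min_mantle_side,
    )
    ref_mean = mantle.ra_mean if mean_domain == "log" else mantle.ra_mean_linear
    if mantle.slope == 0 or ref_mean == 0:
        raise UndefinedReferenceError("mantle reference statistic is zero")

    hw = side // 2
    edge_mask = np.zeros((h, w), dtype=bool)
    edge_mask[hw : h - hw, hw : w - hw] = True
    hidden_mask = np.ones((h, w), dtype=bool)
    if hidden_rois is not None:
        hidden_mask &= ~hidden_rois.mask("hidden_zone", (h, w))

    binner = _binner(side, float(drop_low))
    center_rows = np.arange(hw, h - hw, stride)
    center_cols = np.arange(hw, w - hw, stride)
    n_r, n_c = len(center_rows), len(center_cols)
    slope_grid = np.full((n_r, n_c), np.nan)
    meansim_grid = np.full((n_r, n_c), np.nan)
    gate_grid = np.zeros((n_r, n_c), dtype=bool)

    ref_slope = mantle.slope
    ref_logp = mantle.log_power
    abs_ref_mean = abs(ref_mean)
    for i, cr in enumerate(center_rows):
        r0 = cr - hw
        for j, cc in enumerate(center_cols):
            c0 = cc - hw
            out = _window_stats_fast(pixels[r0 : r0 + side, c0 : c0 + side], binner)
            if out is None:
                continue
            slope_w, ra_mean_w, logp_w = out
            win_mean = ra_mean_w if mean_domain == "log" else 10.0**ra_mean_w
            msim = max(0.0, 1.0 - abs(ref_mean - win_mean) / abs_ref_mean)
            meansim_grid[i, j] = msim
            if msim < threshold:
                continue  # gate fails on the 90% mean-similarity sub-condition
            mw_p = mann_whitney_u(ref_logp, logp_w).p
            if mw_p <= gate_alpha:
                continue  # significantly different means: mask, never plot
            gate_grid[i, j] = True
            slope_grid[i, j] = max(0.0, 1.0 - abs(ref_slope - slope_w) / abs(ref_slope))

    # scatter the computed grid onto the pixel rasters (nearest neighbour
    # for stride > 1)
    slope_sim = np.full((h, w), np.nan)
    mean_sim = np.full((h, w), np.nan)
    gate_mask = np.zeros((h, w), dtype=bool)
    interpolated = np.zeros((h, w), dtype=bool)
    rows_in = np.arange(hw, h - hw)
    cols_in = np.arange(hw, w - hw)
    if len(rows_in) and len(cols_in):
        ri = np.clip(np.rint((rows_in - hw) / stride).astype(int), 0, n_r - 1)
        ci = np.clip(np.rint((cols_in - hw) / stride).astype(int), 0, n_c - 1)
        slope_sim[np.ix_(rows_in, cols_in)] = slope_grid[np.ix_(ri, ci)]
        mean_sim[np.ix_(rows_in, cols_in)] = meansim_grid[np.ix_(ri, ci)]
        gate_mask[np.ix_(rows_in, cols_in)] = gate_grid[np.ix_(ri, ci)]
        if stride > 1:
            is_center_r = np.isin(rows_in, center_rows)
            is_center_c = np.isin(cols_in, center_cols)
            interpolated[np.ix_(rows_in, cols_in)] = ~(
                is_center_r[:, None] & is_center_c[None, :]
            )

    masked_out = ~(edge_mask & hidden_mask)
    slope_sim[masked_out] = np.nan
    slope_sim[~gate_mask] = np.nan

    return SimilarityMap(
        slope_similarity=slope_sim,
        mean_similarity=mean_sim,
        gate_mask=gate_mask,
        edge_mask=edge_mask,
        hidden_mask=hidden_mask,
        interpolated=interpolated,
        threshold=threshold,
        stride=stride,
        mantle_ref=mantle,
        params={
            "drop_low": drop_low,
            "gate_alpha": gate_alpha,
            "mean_domain": mean_domain,
            "mantle_origin": tuple(mantle_origin),
            "mantle_side": side,
        },
    )


def threshold_overlay(
    simmap: SimilarityMap, scene, cmap: str = "viridis"
) -> np.ndarray:
    """Grayscale scene with pixels at or above the similarity threshold
    tinted by a colormap scaled over [threshold, 1]; masked and
    below-threshold pixels are left untouched.  Returns float RGB in [0, 1].
    """
    from matplotlib import colormaps

    pixels = spectral._scene_pixels(scene)
    if pixels.shape != simmap.slope_similarity.shape:
        raise BoundsError("similarity map and scene dimensions differ")
    lo, hi = float(pixels.min()), float(pixels.max())
    gray = (pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(pixels)
    rgb = np.stack([gray] * 3, axis=-1)
    sel = np.isfinite(simmap.slope_similarity) & (
        simmap.slope_similarity >= simmap.threshold
    )
    if sel.any():
        span = max(1.0 - simmap.threshold, 1e-12)
        t = (simmap.slope_similarity[sel] - simmap.threshold) / span
        rgb[sel] = colormaps[cmap](np.clip(t, 0.0, 1.0))[:, :3]
    return rgb


def summarize_region(
    simmap: SimilarityMap, region_mask: np.ndarray, fill: float = 0.0
) -> dict[str, float]:
    """Median similarity and above-threshold fraction inside a region.

    Gate-failed pixels count as ``fill`` (no resemblance was demonstrated
    there); pixels outside the analyzable area are ignored.
    """
    filled = simmap.filled(fill)
    sel = region_mask & simmap.analyzable
    vals = filled[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return {"n": 0.0, "median": float("nan"), "above_threshold_fraction": float("nan")}
    return {
        "n": float(vals.size),
        "median": float(np.median(vals)),
        "above_threshold_fraction": float((vals >= simmap.threshold).mean()),
    }
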