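"""Synthetic camouflage scenes with known spectral structure.

Natural underwater scenes have approximately power-law radial power spectra,
``P(f) ~ f**(-beta)`` with region-specific exponents ``beta``.  This module
synthesises grayscale scenes from that model so that every downstream stage
of the pipeline (preprocessing, spectral statistics, per-pixel mapping,
multi-point group tests) can be exercised against exact ground truth: a
fractal background, embedded objects whose exponents match or mismatch the
animal's mantle patch, a square mantle region, smooth multiplicative
illumination and additive sensor noise.

Textures are built in Fourier space: random phases with deterministic
amplitude ``f**(-beta/2)``, so the expected (and, up to windowing, the
realised) radial power spectrum is a pure power law.  Everything is
deterministic given ``SceneSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .errors import InvalidSpecError

__all__ = [
    "SceneObject",
    "SceneSpec",
    "SceneTruth",
    "make_fractal_texture",
    "render_scene",
    "reference_scene_spec",
    "save_scene",
    "load_scene_spec",
    "save_scene_spec",
    "regions_from_truth",
]

#: label value of the background in truth rasters
BACKGROUND_LABEL = 0

#: gray-level standard deviation given to a unit-gain texture at render time
BASE_CONTRAST = 0.1

#: feather width (px) of the linear blending ramp at object boundaries
FEATHER_PX = 3

#: minimum side of a mantle reference patch, in pixels
MIN_MANTLE_SIDE = 150


@dataclass(frozen=True)
class SceneObject:
    """One embedded object: an ellipse or an irregular blob.

    ``radii`` are the (row, col) semi-axes in pixels.  ``gain`` scales the
    object's texture contrast relative to the scene base contrast; the
    spectral exponent ``beta`` controls its texture statistics.
    """

    shape: str  # "ellipse" | "blob"
    center: tuple[int, int]  # (row, col)
    radii: tuple[float, float]  # (row semi-axis, col semi-axis)
    beta: float
    gain: float = 1.0

    def validate(self, height: int, width: int) -> None:
        if self.shape not in ("ellipse", "blob"):
            raise InvalidSpecError(f"unknown object shape {self.shape!r}")
        if self.beta < 0:
            raise InvalidSpecError("object beta must be >= 0")
        if min(self.radii) <= 0:
            raise InvalidSpecError("object radii must be positive")
        # blobs perturb the radius by up to 35%; demand that envelope fits
        margin = 1.35 if self.shape == "blob" else 1.0
        r, c = self.center
        if (
            r - margin * self.radii[0] < 0
            or r + margin * self.radii[0] > height - 1
            or c - margin * self.radii[1] < 0
            or c + margin * self.radii[1] > width - 1
        ):
            raise InvalidSpecError("object extends outside the image")


@dataclass(frozen=True)
class SceneSpec:
    """Full specification of a synthetic scene.

    ``mantle_box`` is ``((row, col), side)`` of a square patch filled with a
    texture of exponent ``mantle_beta``; it may be ``None`` for scenes
    without an animal.  ``illumination`` is ``(gradient_amplitude,
    length_scale_px)`` of a multiplicative linear ramp along the column
    axis; amplitude is a fraction of the dynamic range.
    """

    width: int
    height: int
    background_beta: float
    objects: tuple[SceneObject, ...] = ()
    mantle_box: tuple[tuple[int, int], int] | None = None
    mantle_beta: float = 2.0
    #: 1-based index of an object whose texture field supplies the mantle
    #: patch (the animal copying that object's pattern); None = independent
    #: texture of exponent ``mantle_beta``
    mantle_from_object: int | None = None
    #: px of same-texture margin rendered (and labelled mantle) around the
    #: box, emulating the rest of the animal's body surrounding the sample
    mantle_margin: int = 0
    illumination: tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width < 16 or self.height < 16:
            raise InvalidSpecError("scene must be at least 16x16 px")
        if self.background_beta < 0 or self.mantle_beta < 0:
            raise InvalidSpecError("beta values must be >= 0")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        for obj in self.objects:
            obj.validate(self.height, self.width)
        if self.mantle_box is not None:
            (r, c), side = self.mantle_box
            if side < MIN_MANTLE_SIDE:
                raise InvalidSpecError(
                    f"mantle_box side {side} < minimum {MIN_MANTLE_SIDE} px"
                )
            m = self.mantle_margin
            if m < 0:
                raise InvalidSpecError("mantle_margin must be >= 0")
            if r - m < 0 or c - m < 0 or r + side + m > self.height \
                    or c + side + m > self.width:
                raise InvalidSpecError(
                    "mantle_box (with its margin) extends outside the image"
                )
        if self.mantle_from_object is not None and not (
            1 <= self.mantle_from_object <= len(self.objects)
        ):
            raise InvalidSpecError("mantle_from_object is not a valid object index")

    @property
    def mantle_label(self) -> int:
        return len(self.objects) + 1


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene.

    ``label_raster`` assigns every pixel exactly one region id (0 =
    background, 1..K = objects in composition order, K+1 = mantle); later
    regions overwrite earlier ones.  ``betas`` maps region id to the
    spectral exponent its texture was drawn with.
    """

    label_raster: np.ndarray
    betas: dict[int, float]
    label_names: dict[int, str]
    illumination_field: np.ndarray
    mantle_box: tuple[tuple[int, int], int] | None = None
    #: object label whose texture the mantle copies, and the box (in scene
    #: coordinates, inside that object) the copied patch was read from
    copied_object_label: int | None = None
    mantle_source_box: tuple[tuple[int, int], int] | None = None

    def mask(self, label: int) -> np.ndarray:
        return self.label_raster == label


def make_fractal_texture(width: int, height: int, beta: float, seed: int) -> np.ndarray:
    """Synthesise a 1/f^beta fractal texture, rescaled to [0, 1].

    The texture is the inverse FFT of a spectrum with deterministic
    amplitude ``f**(-beta/2)`` (zero at DC) and the random Fourier phases of
    a seeded white-noise field, so the radial power spectrum is a power law
    by construction and the output is real and deterministic given ``seed``.
    """
    if width < 16 or height < 16:
        raise InvalidSpecError("texture dimensions must be >= 16 px")
    if beta < 0:
        raise InvalidSpecError("beta must be >= 0")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((height, width))
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** (-beta / 2.0), 0.0)
    mod = np.abs(spectrum)
    # keep only the (Hermitian-symmetric) phases of the white field
    phases = np.where(mod > 0, spectrum / np.where(mod > 0, mod, 1.0), 0.0)
    tex = np.fft.ifft2(amp * phases).real
    lo, hi = tex.min(), tex.max()
    if hi - lo <= 0:
        return np.zeros_like(tex)
    return (tex - lo) / (hi - lo)


def _standardize(tex: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance version of a texture (contrast-neutral)."""
    sd = tex.std()
    if sd == 0:
        return np.zeros_like(tex)
    return (tex - tex.mean()) / sd


def _object_mask(obj: SceneObject, shape: tuple[int, int], seed: int) -> np.ndarray:
    """Boolean mask of an ellipse, or a blob = ellipse with a seeded
    low-order Fourier perturbation of its angular radius (up to 35%)."""
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    dy = (rr - obj.center[0]) / obj.radii[0]
    dx = (cc - obj.center[1]) / obj.radii[1]
    rho = np.hypot(dy, dx)
    if obj.shape == "ellipse":
        return rho <= 1.0
    rng = np.random.default_rng(seed)
    amps = rng.uniform(-1.0, 1.0, size=4)
    amps *= 0.35 / max(1.0, np.abs(amps).sum())
    phis = rng.uniform(0, 2 * np.pi, size=4)
    theta = np.arctan2(dy, dx)
    boundary = 1.0
    for k, (a, p) in enumerate(zip(amps, phis), start=2):
        boundary = boundary + a * np.cos(k * theta + p)
    return rho <= boundary


def _feather_alpha(mask: np.ndarray, feather: float = FEATHER_PX) -> np.ndarray:
    """Blending weight: 1 in the mask interior, linear ramp to 0 over
    ``feather`` px approaching the boundary from inside."""
    if not mask.any():
        return np.zeros(mask.shape)
    dist = distance_transform_edt(mask)
    return np.minimum(dist / feather, 1.0)


def illumination_field(
    height: int, width: int, amplitude: float, length_scale: float
) -> np.ndarray:
    """Multiplicative illumination: linear ramp along columns from
    ``1 - amplitude`` to ``1 + amplitude`` over ``length_scale`` px."""
    if amplitude == 0:
        return np.ones((height, width))
    x = np.arange(width, dtype=float)
    t = np.clip(x / max(length_scale, 1.0), 0.0, 1.0)
    return np.ones((height, 1)) * (1.0 + amplitude * (2.0 * t - 1.0))[None, :]


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render a scene and its ground truth.

    Composition order: background texture, then objects in listed order
    (later objects overwrite earlier ones, feathered over <=3 px), then the
    mantle box, then multiplicative illumination, then additive Gaussian
    noise.  Each texture is standardised and given gray-level SD
    ``BASE_CONTRAST * gain`` about mid-gray, so regions of equal exponent
    and gain have the same expected power spectrum regardless of the
    realised dynamic range of their parent textures.
    """
    spec.validate()
    h, w = spec.height, spec.width
    ss = np.random.SeedSequence(spec.seed)
    n_obj = len(spec.objects)
    children = ss.spawn(2 * n_obj + 3)  # bg, (tex+shape per object), mantle, noise
    child_seed = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    canvas = 0.5 + BASE_CONTRAST * _standardize(
        make_fractal_texture(w, h, spec.background_beta, child_seed[0])
    )
    label = np.full((h, w), BACKGROUND_LABEL, dtype=np.int32)
    betas = {BACKGROUND_LABEL: spec.background_beta}
    names = {BACKGROUND_LABEL: "background"}

    object_fields = []
    for k, obj in enumerate(spec.objects, start=1):
        tex = 0.5 + BASE_CONTRAST * obj.gain * _standardize(
            make_fractal_texture(w, h, obj.beta, child_seed[2 * k - 1])
        )
        object_fields.append(tex)
        mask = _object_mask(obj, (h, w), child_seed[2 * k])
        alpha = _feather_alpha(mask)
        canvas = alpha * tex + (1.0 - alpha) * canvas
        label[mask] = k
        betas[k] = obj.beta
        names[k] = f"object_{k}"

    copied_label = None
    source_box = None
    if spec.mantle_box is not None:
        (r0, c0), side = spec.mantle_box
        m = spec.mantle_margin
        big = side + 2 * m
        if spec.mantle_from_object is not None:
            # the animal copies the object's pattern: the mantle patch is a
            # window of that object's texture field, centred on the object
            src = object_fields[spec.mantle_from_object - 1]
            cr, cc = spec.objects[spec.mantle_from_object - 1].center
            pr = min(max(cr - big // 2, 0), h - big)
            pc = min(max(cc - big // 2, 0), w - big)
            patch = src[pr : pr + big, pc : pc + big]
            mantle_beta = spec.objects[spec.mantle_from_object - 1].beta
            copied_label = spec.mantle_from_object
            source_box = ((pr + m, pc + m), side)
        else:
            # an independent patch of a full-size field, so the mantle has
            # the same low-frequency content as equally sized windows of
            # the other regions
            field = 0.5 + BASE_CONTRAST * _standardize(
                make_fractal_texture(w, h, spec.mantle_beta, child_seed[2 * n_obj + 1])
            )
            pr = min(max(r0 - m, 0), h - big)
            pc = min(max(c0 - m, 0), w - big)
            patch = field[pr : pr + big, pc : pc + big]
            mantle_beta = spec.mantle_beta
        canvas[r0 - m : r0 - m + big, c0 - m : c0 - m + big] = patch
        label[r0 - m : r0 - m + big, c0 - m : c0 - m + big] = spec.mantle_label
        betas[spec.mantle_label] = mantle_beta
        names[spec.mantle_label] = "mantle"

    illum = illumination_field(h, w, *spec.illumination)
    canvas = canvas * illum
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(child_seed[2 * n_obj + 2])
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=canvas.shape)

    canvas = np.clip(canvas, 0.0, None)
    peak = canvas.max()
    if peak > 1.0:
        canvas = canvas / peak

    truth = SceneTruth(
        label_raster=label,
        betas=betas,
        label_names=names,
        illumination_field=illum,
        mantle_box=spec.mantle_box,
        copied_object_label=copied_label,
        mantle_source_box=source_box,
    )
    return canvas, truth


def reference_scene_spec(seed: int = 0, size: int = 512) -> SceneSpec:
    """The package's reference test world: a 512x512 scene with background
    exponent 1.0, a 150-px mantle box of exponent 2.5 (top-left quadrant),
    one large matching object (beta 2.5) below it, one equally large
    distractor object of background-like texture (beta 1.0) to the right,
    a 10% multiplicative illumination ramp across the full width, and mild
    sensor noise (SD 0.005 gray levels, ~5% of the texture contrast).

    The matching object sits near the mantle along the illumination ramp —
    the configuration the biology implies, since an animal imitates an
    object in its *immediate* surroundings — so that residual illumination
    gain (which a subtractive top-hat cannot remove) stays small between
    the two regions.
    """
    if size != 512:
        raise InvalidSpecError("the reference scene family is defined at 512 px")
    return SceneSpec(
        width=size,
        height=size,
        background_beta=1.0,
        objects=(
            # matching object: same exponent as the mantle; large enough
            # that the mantle-sized sample box plus the composed filter
            # support (top-hat SE + Gaussian kernel, 26 px) fits fully
            # inside its interior, so no sampled window's morphology
            # crosses the object boundary
            SceneObject("ellipse", center=(330, 160), radii=(145, 145), beta=2.5),
            # distractor: background-like exponent
            SceneObject("ellipse", center=(140, 380), radii=(110, 115), beta=1.0),
        ),
        mantle_box=((30, 30), 150),
        mantle_beta=2.5,
        # the animal copies the matching object's pattern, and the sample
        # box sits inside a larger body of the same texture; the margin
        # exceeds the composed filter support (top-hat SE radius 25 plus
        # the Gaussian kernel radius), keeping cross-boundary morphology
        # out of every mantle window
        mantle_from_object=1,
        mantle_margin=30,
        illumination=(0.1, size),
        noise_sigma=0.005,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialisation

def save_scene(
    scene: np.ndarray, truth: SceneTruth, prefix, bitdepth: int = 16
) -> dict[str, str]:
    """Write scene PNG (8- or 16-bit), truth label PNG and a JSON sidecar
    of region exponents; returns the file manifest.  Gray values live in
    [0, 1] float until this point and are quantised only here."""
    import imageio.v3 as iio

    prefix = str(prefix)
    if bitdepth == 16:
        img = np.round(scene * 65535).astype(np.uint16)
    elif bitdepth == 8:
        img = np.round(scene * 255).astype(np.uint8)
    else:
        raise InvalidSpecError("bitdepth must be 8 or 16")
    scene_path = prefix + "_scene.png"
    label_path = prefix + "_labels.png"
    sidecar_path = prefix + "_truth.json"
    iio.imwrite(scene_path, img)
    if truth.label_raster.max() > 255:
        raise InvalidSpecError("more than 255 regions cannot be written as 8-bit PNG")
    iio.imwrite(label_path, truth.label_raster.astype(np.uint8))
    with open(sidecar_path, "w") as fh:
        json.dump(
            {
                "betas": {str(k): v for k, v in truth.betas.items()},
                "label_names": {str(k): v for k, v in truth.label_names.items()},
            },
            fh,
            indent=2,
        )
    return {"scene": scene_path, "labels": label_path, "truth": sidecar_path}


def _spec_to_dict(spec: SceneSpec) -> dict:
    return {
        "width": spec.width,
        "height": spec.height,
        "background_beta": spec.background_beta,
        "mantle_beta": spec.mantle_beta,
        "mantle_box": None
        if spec.mantle_box is None
        else [list(spec.mantle_box[0]), spec.mantle_box[1]],
        "mantle_from_object": spec.mantle_from_object,
        "mantle_margin": spec.mantle_margin,
        "illumination": list(spec.illumination),
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "objects": [
            {
                "shape": o.shape,
                "center": list(o.center),
                "radii": list(o.radii),
                "beta": o.beta,
                "gain": o.gain,
            }
            for o in spec.objects
        ],
    }


def save_scene_spec(spec: SceneSpec, path) -> None:
    """Write a SceneSpec to YAML (or JSON if the path ends in .json)."""
    d = _spec_to_dict(spec)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            import yaml

            yaml.safe_dump(d, fh)


def load_scene_spec(path) -> SceneSpec:
    """Read a SceneSpec from a YAML or JSON config file."""
    path = str(path)
    with open(path) as fh:
        if path.endswith(".json"):
            d = json.load(fh)
        else:
            import yaml

            d = yaml.safe_load(fh)
    objects = tuple(
        SceneObject(
            shape=o["shape"],
            center=tuple(o["center"]),
            radii=tuple(o["radii"]),
            beta=float(o["beta"]),
            gain=float(o.get("gain", 1.0)),
        )
        for o in d.get("objects", [])
    )
    mb = d.get("mantle_box")
    spec = SceneSpec(
        width=int(d["width"]),
        height=int(d["height"]),
        background_beta=float(d["background_beta"]),
        objects=objects,
        mantle_box=None if mb is None else ((int(mb[0][0]), int(mb[0][1])), int(mb[1])),
        mantle_beta=float(d.get("mantle_beta", 2.0)),
        mantle_from_object=d.get("mantle_from_object"),
        mantle_margin=int(d.get("mantle_margin", 0)),
        illumination=tuple(d.get("illumination", (0.0, 0.0))),
        noise_sigma=float(d.get("noise_sigma", 0.0)),
        seed=int(d.get("seed", 0)),
    )
    spec.validate()
    return spec


def regions_from_truth(
    truth: SceneTruth,
    object_labels: Sequence[int] = (),
    erode_px: int = 28,
    substrate_margin: int = 0,
):
    """Build a :class:`~backmatch.regions.RegionSet` from ground truth.

    The mantle label becomes ``octopus_mantle``, the given object labels
    become ``distinct_object`` regions and the background becomes
    ``general_substrate``.  Object and substrate masks are eroded by
    ``erode_px`` (default: feather width + top-hat SE radius), emulating an
    annotator who stays clear of region borders: samples then contain no
    feather-blended pixels and no pixels whose morphological neighbourhood
    crosses into another region.  ``substrate_margin`` additionally trims
    the substrate at the image border.
    """
    from scipy.ndimage import binary_erosion

    from .regions import Region, RegionSet

    def _eroded(mask: np.ndarray) -> np.ndarray:
        if erode_px <= 0:
            return mask
        return binary_erosion(mask, np.ones((3, 3), dtype=bool), iterations=erode_px)

    regs = []
    if truth.mantle_box is not None:
        # the sample box itself; its margin (part of the mantle label) only
        # shields the box from cross-boundary morphology
        (r, c), side = truth.mantle_box
        regs.append(Region("octopus_mantle", rect=(r, c, side, side)))
    for k in object_labels:
        if k == truth.copied_object_label and truth.mantle_source_box is not None:
            # the annotation the similarity map itself suggests: the patch
            # of the object whose pattern the animal reproduces, matched in
            # size to the mantle sample box
            (sr, sc), sside = truth.mantle_source_box
            regs.append(Region("distinct_object", rect=(sr, sc, sside, sside)))
        else:
            regs.append(Region("distinct_object", mask=_eroded(truth.mask(k))))
    substrate = truth.mask(BACKGROUND_LABEL).copy()
    if substrate_margin > 0:
        substrate[:substrate_margin, :] = False
        substrate[-substrate_margin:, :] = False
        substrate[:, :substrate_margin] = False
        substrate[:, -substrate_margin:] = False
    regs.append(Region("general_substrate", mask=_eroded(substrate)))
    return RegionSet(regions=regs)
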