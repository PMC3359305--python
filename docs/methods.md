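# Methods

This note documents the models and procedures implemented in `backmatch`,
the parameter choices that matter, what the synthetic world does and does
not emulate, and the numerical conventions fixed by the package.

## The texture descriptor

For a square patch of side `s`, the patch is mean-subtracted and discrete
Fourier transformed; the power spectrum is normalised so that its sum
equals the patch's sum of squared deviations (Parseval convention), which
makes power comparable across windows of equal size. Spectrum pixels are
binned by their integer-rounded radial distance from the DC bin; the
profile is truncated at the Nyquist radius `floor(s/2)`, the DC bin is
always discarded, and annuli below 2% of the Nyquist radius are discarded
as well (`drop_low = 0.02`) — near-DC bins hold very few pixels and spike
erratically. On the retained annuli, ordinary least squares of
log10(mean power) on log10(radius) yields:

* **RA-slope** — the texture statistic; for `P(f) ∝ f^(−β)` textures it
  estimates `−β`. Base-invariant.
* **RA-mean** — the arithmetic mean of log10(annulus power), i.e. the mean
  height of the log-log plot. Base-dependent (log10 throughout).
* **RA-intercept**, **r²**, and a one-sample Kolmogorov–Smirnov p-value of
  the retained log-power sample against a normal with the sample's own
  mean and SD. `ks_p` is reported, never used as a gate.

No window taper is applied before the FFT by default (a Hann option would
change absolute slopes; the protocol this package reimplements used none).
Annulus rounding, truncation and exclusion rules are identical in the
optimised sliding path and the brute-force oracle used in tests.

## Preprocessing chain

Analysis runs on a single-channel raster produced in exactly this order:

1. **Green channel** of the RGB photograph (closest to a cephalopod's
   single visual pigment; lowest-noise channel under water). Synthetic
   grayscale scenes record a `grayscale_input` step instead.
2. **Gaussian filter**, parameterised the MATLAB way: `delta = 2` is the
   kernel size in pixels (the protocol's printed parameter) and
   `sigma = 0.5` px is the standard deviation (MATLAB's
   `fspecial('gaussian', hsize)` default for a bare size argument).
3. **White top-hat**: image minus its morphological opening by a disk of
   radius 25 px (`se_radius = 25`), removing smooth structure larger than
   the SE — in practice the illumination field.

Both filters use reflective boundaries so that windows near the image edge
are not biased by injected borders. Downstream stages refuse a scene whose
recorded provenance deviates from this chain, because spectral statistics
are only comparable between identically filtered patches.

**Why sigma = 0.5 and not 2.** Interpreting the bare "2" as the Gaussian
standard deviation attenuates the power spectrum by
`exp(−4π²σ²f²)` ≈ 17 decades at the window Nyquist. Measured on power-law
textures, the fitted slopes of β = 1.0 and β = 2.5 patches then collapse
onto the same value (separation 0.00–0.12, sign-unstable): the spectrum
tail is dominated by the common Gaussian rolloff and by the broadband
creases the nonlinear top-hat regenerates, and the method loses the very
texture sensitivity it exists to provide. Under the kernel-size reading
(σ = 0.5) the same patches separate by 1.36 ± 0.05 slope units. A method
that demonstrably discriminated natural textures cannot have used the
signal-destroying parameterisation, so the kernel-size reading is adopted;
`sigma` remains an explicit argument for sensitivity analysis.

**What the top-hat does and does not correct.** A subtractive top-hat
removes the smooth additive/offset component of uneven illumination (a 50%
full-width multiplicative ramp leaves a left/right mean difference of 6% of
the dynamic range, down from 19%). It cannot remove the multiplicative
*gain* a light field applies to texture contrast — `tophat(c·T) = c·tophat(T)`
for smooth `c` — so window power still scales with the local illumination
squared. This is why the RA-mean gate (below) operates on the log-power
statistic, and why the per-pixel method is most reliable when the compared
regions sit under similar illumination.

## Per-pixel method

A mantle-sized window (the reference patch must be ≥150 px on a side;
comparison windows only need ≥16) slides across the preprocessed scene at
stride 1 (configurable; skipped pixels take the nearest computed value and
are flagged). Per position:

* **Mean gate** — the window's RA-mean must be ≥90% similar to the
  mantle's, and a two-sided Mann–Whitney U test between the two retained
  log-power samples must be non-significant at α = 0.05. Windows failing
  the gate are masked: no similarity is reported there, matching the
  protocol's rule that positions with significantly different means are
  never plotted. Both sub-conditions are recorded separately.
* **Slope similarity** — `max(0, 1 − |slope_ref − slope_win|/|slope_ref|)`,
  assigned to the window's central pixel (`floor(side/2)` offset from the
  window's top-left; fixed floor convention for even sides).

The map is undefined inside a border of exactly `floor(side/2)` px (the
window would leave the image) and inside user-annotated hidden zones
(scene areas the animal cannot see from its position). The overlay tints
pixels at or above the 0.90 threshold with a colormap scaled over
[threshold, 1].

**Similarity formula.** The protocol's difference formula is not
recoverable from its source, so the package adopts the relative absolute
difference with clamping — it makes "90% similarity" unitless and
well-defined — and applies the *same* formula to slope and to RA-mean. The
RA-mean comparison is made on the log-domain statistic itself (the mean of
the log-log plot, the same object the regression summarises). The
linear-domain alternative (`mean_domain="linear"`, comparing `10**ra_mean`)
is available but far stricter: local power of natural-statistics textures
fluctuates by more than ±10% between same-texture windows (measured ~0.05
decades ≈ 12% for mantle-sized windows of β = 2.5 fields), so the linear
band rejects about half of genuinely matching windows. A zero reference
statistic raises an undefined-reference error and masks the pixel.

## Multi-point method

Each required class (`octopus_mantle`, `distinct_object`,
`general_substrate`) is sampled with 30 random 100×100 px squares (origins
uniform over all positions whose square fits in the region; origins are
distinct when the region offers enough positions, and overlap between
squares is expected and allowed — a 150 px mantle box admits only a 51×51
origin grid). Per-square slopes feed two-sided Mann–Whitney U tests
(mantle vs object, mantle vs substrate; no multiple-testing correction by
default, a Holm option exists) and a tie-corrected Kruskal–Wallis test
across the three classes. The rank tests are implemented from first
principles — exact enumeration of the U distribution for
`min(n1, n2) ≤ 8` without ties, otherwise the normal/χ² approximation with
tie and continuity corrections — and are cross-checked against independent
library implementations in the test suite. Degenerate inputs (all values
identical) return p = 1 and are flagged.

**Statistical caveat for clustered samples.** Thirty squares drawn from a
150² box overlap heavily, so they are positively correlated and the rank
tests' independence assumption is violated. Measured consequences, which
anyone using this protocol on real data should know: two groups drawn from
the *same* box of one homogeneous texture already reject at ~7% (nominal
5%); two groups from *separated* boxes of one homogeneous texture reject
~82% of the time, because the realised local slope of a finite texture
varies spatially. "Same texture class" is therefore not a usable null for
clustered sampling — only content-matched regions are. The package's null
calibration (`null_kw_rejection_rate`) instead assigns group labels
randomly to slopes pooled from one texture, which is exchangeable by
construction and holds the nominal level.

## The synthetic world

`make_fractal_texture` builds textures in Fourier space: deterministic
amplitude `f^(−β/2)` (zero DC) with the random Hermitian phases of a
seeded white-noise field. The radial spectrum is a power law by
construction; the slope estimator recovers −β to within ±0.003 at 512 px,
so calibration failures indicate pipeline defects, not generator noise.

`render_scene` composes: a background texture; elliptical or irregular
("blob") objects in listed order, each blended over a ≤3 px linear feather
ramp to avoid spurious step-edge spectra; a square mantle patch; a
multiplicative linear illumination ramp (mean 1 ± amplitude across the
length scale); additive Gaussian pixel noise; and records a per-pixel
ground-truth label raster (later regions overwrite earlier ones) with
per-region exponents. Every texture is standardised to a fixed gray-level
SD (0.1 about mid-gray, times the object's `gain`), so regions of equal
exponent and gain have equal expected power regardless of the realised
range of their parent fields. Gray values stay float in [0, 1]; they are
quantised to 8/16 bits only when written to PNG.

The **reference scene family** (`reference_scene_spec`, 512², seeded)
encodes the biology the pipeline is meant to detect: the mantle patch
*copies* the texture field of one large embedded object
(`mantle_from_object`) — deceptive resemblance is imitation of a specific
object, not membership of the same texture class (see the caveat above:
independent same-β realisations are reliably told apart). The sample box
sits inside a 30 px margin of the same texture, emulating the rest of the
animal's body and keeping every sampled window's composed filter support
(top-hat SE radius 25 + Gaussian kernel radius) inside one region; the
matching object's radii (145 px) satisfy the same support condition for
the object-side samples. Illumination amplitude is 0.1 (a mild sunlit-
shallow-water gradient) and sensor noise SD is 0.005 gray levels (~5% of
texture contrast) — chosen once as realistic, not calibrated to tests.

What the generator does **not** emulate: real skin patterning
(chromatophore patterns are not Gaussian random fields), phase structure
of natural scenes (edges, occlusion), wavelength-dependent attenuation,
caustics, and camera optics. A green test therefore establishes that the
pipeline recovers planted spectral structure under its own model — not
that the model captures everything about field photographs.

## Numerical conventions

* log base 10 everywhere; slope is base-invariant.
* Annulus binning by `rint` (round-half-to-even) of the radius; the test
  oracle uses the same rule.
* Regression requires ≥3 positive-power annuli; zero-power annuli are
  excluded with a recorded count.
* KS p-value is NaN when the log-power sample is constant.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence.spawn`; identical inputs give
  bit-identical rasters, maps and reports.
* Degenerate top-hat (SE radius exceeding half the image) warns but
  computes; the opening is meaningless within one SE radius of the image
  border, and tests treat that band as undefined.

## Known limitations

* The per-pixel mean gate inherits the top-hat's inability to correct
  multiplicative illumination gain; strong gradients (≫10%) between the
  mantle and a genuinely matching region will fail the gate honestly.
* With clustered, overlapping samples the Mann–Whitney test is mildly
  anti-conservative (~7% at nominal 5%); on the reference family the
  object-vs-mantle non-rejection rate is ~88% rather than the ~95% an
  independent-sample analysis would suggest.
* Runtime scales with window count: a 512² scene at stride 2 with a 150 px
  window takes ~20 s on one CPU; stride is the intended cost control and
  is recorded in every report.
* Slopes are orientation-averaged by design; anisotropic textures with
  equal radial averages are indistinguishable to this descriptor.
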