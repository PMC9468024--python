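# Methods

## Problem and scope

Screening plunge-frozen cryo-EM grids for usable vitreous-ice thickness
normally consumes electron-microscope time. Reflected-light interferometry
offers a fast alternative: a grid illuminated simultaneously at three
wavelengths (433/517/613 nm through a triple-bandpass filter) shows
thin-film interference colours that encode the local ice thickness. This
package implements the analysis side of that approach — grid-square
detection, five-class ice-quality classification with confidence, and
absolute thickness from energy-filtered EM pairs — together with a
physics-based synthetic-scene generator that supplies labelled training
and validation data, since no labelled interferometric corpus of coated
grids is publicly available.

## Optical model

The ice film is modelled as a free-standing homogeneous layer of
refractive index `n = 1.31` (low-density amorphous ice in the visible;
configurable) in air. At normal incidence the two interfaces have Fresnel
amplitude reflectances `r1 = (1 − n)/(1 + n) = −r2 ≈ −0.134`, and the
two-beam reflectance is

    R(t, λ) = r1² + r2² + 2·r1·r2·cos(4π·n·t/λ)

periodic in thickness with period `λ/(2n)` (~165 nm at 433 nm). Multiple
internal reflections are neglected: with |r| ≈ 0.13 the first neglected
term is below 2% of the modulation depth. Each colour channel
band-averages `R` over the filter passband with 5-point Gauss–Legendre
quadrature; the passband FWHM defaults to 20 nm per channel (typical for
multiband filters; the exact widths are instrument-specific). The model
is a deliberate idealisation chosen to reproduce the qualitative fringe
phenomenology of real interferograms — it is not calibrated against any
particular instrument, and no such calibration is published. Whether ice
inside foil holes should instead be modelled on a carbon substrate
(asymmetric stack) is an open choice; the default is the symmetric
free-standing film, and `FilmStack` accepts asymmetric indices.

## Synthetic scenes

Scenes emulate a 200-mesh copper grid with an R2/1 holey foil: 125 µm
pitch, 35 µm bars, 2 µm holes with 1 µm spacing, at camera pixel sizes of
1.30/0.65/0.325 µm per pixel for the 5×/10×/20× objectives. Rendering
evaluates the geometry at each pixel centre through an exact inverse
rotation, so ground-truth masks match the image to the pixel and
arbitrary grid rotations introduce no resampling error. Bars render at a
fixed bright display value (0.95); film reflectance is scaled so the
quarter-wave maximum maps to 0.85; the foil adds a small uniform offset
(0.02); additive Gaussian channel noise (default SD 0.01) is applied
last.

Per-square thickness fields are continuous functions (a class-dependent
mean plus a six-term random cosine surface with correlation lengths of
0.6–2.5 square widths, plus Gaussian bumps), so they can be sampled
exactly at rotated pixel positions. The class conditions are:

| class | name      | per-square mean bin (nm) | construction |
|-------|-----------|--------------------------|--------------|
| 0     | bad       | base 25–60               | mid-range film carrying a defect: punched hole or scratch (film removed) or opaque dust |
| 1     | too thin  | 6–20 (centre 13, SD 3)   | near-uniform, spatial SD 1.5 nm |
| 2     | optimal   | 20–50 (centre 40, SD 5)  | near-uniform, spatial SD 3 nm |
| 3     | thicker   | 50–70 (centre 56, SD 4)  | centre-weighted puddle (12–22 nm bump, σ 0.2–0.3 of the square) |
| 4     | too thick | 70–95                    | 64–72 nm base plus a droplet peaking 420–480 nm above it (σ 0.06), i.e. several full fringes |

Class means are drawn from truncated normals inside their bins, so the
bins partition ground truth; bins are anchored to the validated regime in
which class-2 squares centre near 40 nm, class-3 near 56 nm, and square
means span roughly 6–91 nm. Class-0 squares carry defects over a
mid-range base because defects occur in otherwise ordinary ice; the base
range is a generator choice. All draws derive from
`numpy.random.default_rng` seeded per square, making every generator
bit-reproducible.

What the generator does *not* emulate: surface roughness of real grid
bars, carbon-film contrast structure, vignetting and illumination
gradients, chromatic aberration, partially devitrified ice, and the
labelling noise of human annotators. Accuracies measured on these scenes
therefore demonstrate that the pipeline's machinery is correct and
learnable, not that the same numbers transfer to any particular
instrument's images.

## Energy-filter thickness model

Zero-loss filtering attenuates the recorded intensity as
`I_zl = I_t · exp(−t/λ_inel)`; inversion gives
`t = λ_inel · ln(I_t/I_zl)` per pixel. `λ_inel` defaults to 322 nm, the
standard literature value for vitreous ice at 300 kV, and is fully
configurable because published thickness measurements rarely state their
calibration. Negative apparent thicknesses (noise) are clipped to zero
and flagged rather than propagated; pixels with non-positive intensity
are marked invalid. Foil holes are detected by thresholding the bright
hole lattice (Otsu), filtering components by circularity and, when the
hole diameter is configured, by radius; border-cut holes are dropped. A
grid square is summarised by the mean over 10 holes drawn without
replacement (seeded), each hole contributing the mean over its disc
eroded by 2 px to avoid Fresnel edge fringes; the aperture rule is ours,
as no standard exists.

## Segmentation

The default path is classical and fully deterministic: the metal bars are
the brightest colour-neutral structure, so thresholding the channel-mean
image at 0.90 (configurable; `None` selects Otsu) separates tiles from
background, followed by a 3×3 median filter. Post-processing fills holes
inside each 4-connected component (4-connectivity prevents diagonally
adjacent squares merging through bar-gap corners), removes components
with bounding-box aspect ratio above 1.5 or area below 25% of the median
component area, keeps border-touching partial squares but flags them, and
orders detections row-major.

A learned path trains a small MLP (16 hidden units) on per-pixel
features (raw channels, Gaussian local mean and SD, Sobel gradient
magnitude) with the same SGD recipe as the classifier, replacing the
transfer-learned encoder–decoder networks used in practice; training a
compact model from scratch on synthetic data keeps the pipeline
reproducible from nothing, which is the property under test here — not
the fidelity of any particular pre-trained backbone.

## Orientation

The grid angle is estimated by scanning radon-transform projection
angles and maximising the variance of the projection profile, which
peaks when the projection direction runs along the bars; the transform
is named in the field's workflow, the variance criterion is our choice.
The image is padded to square with a median fill and downsampled to ≤384
px; a 1° coarse pass over [0°, 90°) is refined at the requested
resolution (default 0.25°) in a ±1.5° window, the result folded into
[−45°, 45°) by the mesh's 90° symmetry, ties breaking toward smaller
|angle|. Flat images return 0° with a low-confidence flag. Deskewing
uses bilinear rotation about the centre with a grown canvas, filling new
pixels with the 90th-percentile intensity (the bright bars), so filled
corners segment as background.

## Training recipe

Both trainable stages use stochastic gradient descent with momentum 0.9,
L2 weight decay 0.005, and a piecewise learning schedule starting at
α = 0.001 and dropping 30% every 4th schedule tick
(`lr(k) = α·0.7^⌊k/4⌋`); validation runs on the same cadence. One
schedule tick is one epoch (one full pass): with per-mini-batch ticks the
rate would vanish after ~60 gradient steps, which cannot train a model
from scratch; the tick unit and cadence are configurable. Training is
fully seeded (initialisation, shuffling, splits) and reproduces
bit-identical traces.

The tile classifier is a compact model: interpretable image features
(6×6 colour block means and block texture SDs, channel order statistics,
dark-pixel and colour-outlier fractions, gradient energy, centre-rim
contrast — 177 dimensions) standardised and fed to softmax networks with
two hidden layers (64, 32) under cross-entropy. Five seeded members are
trained and their probability vectors averaged, which damps the
initialisation and shuffling variance of individual members. The feature
set mirrors the physics: mean colour encodes mean thickness (classes
1–3), fringe texture flags droplets (class 4), dark/outlier fractions
flag defects (class 0), centre-rim contrast flags puddles (class 3).
Class balance is handled by a stratified split. The training corpus is
harvested through the detection pipeline itself (deskew → segment →
crop, labels read from the generator's ground truth at the tile centre),
so training crops have exactly the statistics of production crops.

Deskewing grows the canvas, so a square cut by the original image edge
no longer touches the border of the rotated frame even though part of
its crop is background fill. The pipeline therefore maps each detection's
bounding-box corners back to the original frame and flags any detection
extending past it as a border (partial) tile; partial tiles keep their
detection and classification but are excluded from the training harvest
and from accuracy bookkeeping, exactly like squares that touch the raw
image border.

## Problem sizes and numerical choices

The benchmark corpus is 120 synthetic 512×512 images at 5× (generated in
chunks of 40 to bound memory) with rotations uniform in ±40°, yielding
≥2000 non-border tiles — a deliberately
compact stand-in for the thousands of hand-labelled squares a real
deployment would use. Segmentation is validated on 30 images (10 per
magnification). Crops are 128×128 with an 8% bounding-box inset to trim
bar remnants. The reflectance LUT used in rendering is sampled at
0.05 nm (interpolation error < 1e-4 in reflectance). Report JSON omits
wall-clock timing (kept on the in-memory object) so repeated runs are
byte-identical. Folder watching polls (default 2 s) with a
modification-time settling delay instead of OS notification APIs, for
portability.

## Known limitations

- The optical display mapping (bar value, film gain, support offset) is
  a rendering convention, not radiometry; absolute colours of real
  cameras will differ, so a classifier trained here must be retrained on
  real labelled images before deployment.
- The two-beam model ignores substrate asymmetry, oblique incidence and
  coherence effects; fringe contrast on carbon-supported films will be
  lower than simulated.
- Thickness summaries inherit whatever `λ_inel` calibration is supplied;
  absolute agreement with any published 6–91 nm measurement is a
  structural property of the generator bins, not an independent
  measurement.
- Hole detection assumes a regular bright hole lattice at low
  magnification; heavily contaminated squares defeat it.
- Only square meshes are supported; hexagonal grids are out of scope.
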