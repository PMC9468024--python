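"""Absolute ice thickness from energy-filtered / unfiltered EM image pairs.

Zero-loss energy filtering removes inelastically scattered electrons, so
the filtered intensity decays with material thickness as
``I_zl = I_t * exp(-t / lam_inel)``. Inverting per pixel,

    t = lam_inel * ln(I_t / I_zl)

gives an absolute thickness map. ``lam_inel`` defaults to 322 nm, the
literature inelastic mean free path of vitreous ice at 300 kV; it is
configurable for other voltages or calibrations.

A grid square is summarised by the mean thickness inside 10 randomly
chosen foil holes (interior pixels only, the disc eroded by 2 px to
avoid edge fringes), reported as mean +/- SD over the 10 hole means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, filters
import tifffile

__all__ = ["EMPair", "ThicknessMap", "SquareSummary", "thickness_map",
           "detect_holes", "square_summary", "LAMBDA_INELASTIC_300KV"]

#: inelastic mean free path of vitreous ice at 300 kV, nm
LAMBDA_INELASTIC_300KV = 322.0


@dataclass
class EMPair:
    """Matched unfiltered / zero-loss-filtered low-magnification EM images."""

    unfiltered: np.ndarray   # I_t, counts
    filtered: np.ndarray     # I_zl, counts
    lam_inel: float = LAMBDA_INELASTIC_300KV
    pixel_size_nm: float = 130.0

    def __post_init__(self):
        self.unfiltered = np.asarray(self.unfiltered, dtype=float)
        self.filtered = np.asarray(self.filtered, dtype=float)
        if self.unfiltered.shape != self.filtered.shape:
            raise ValueError("filtered and unfiltered images must share a shape")
        if self.lam_inel <= 0:
            raise ValueError("inelastic mean free path must be positive")

    @classmethod
    def from_tiffs(cls, unfiltered_path, filtered_path,
                   lam_inel: float = LAMBDA_INELASTIC_300KV,
                   pixel_size_nm: float = 130.0) -> "EMPair":
        return cls(tifffile.imread(unfiltered_path),
                   tifffile.imread(filtered_path), lam_inel, pixel_size_nm)


@dataclass
class ThicknessMap:
    """Per-pixel ice thickness in nm with a validity mask."""

    t_nm: np.ndarray
    valid: np.ndarray        # pixels with positive intensities
    clipped: np.ndarray      # pixels whose negative log-ratio was clipped to 0
    pixel_size_nm: float = 130.0

    def save(self, path) -> None:
        tifffile.imwrite(path, self.t_nm.astype(np.float32))


@dataclass
class SquareSummary:
    """Representative thickness of one grid square from sampled holes."""

    square_id: int
    hole_means: np.ndarray   # per-hole mean thickness, nm
    mean_nm: float
    sd_nm: float


def thickness_map(pair: EMPair) -> ThicknessMap:
    """Pixel-wise thickness ``t = lam_inel * ln(I_t / I_zl)``.

    Exact inverse of the zero-noise forward model. Pixels with a
    non-positive intensity are marked invalid; negative apparent
    thicknesses (noise pushing I_zl above I_t) are clipped to 0 and
    flagged in ``clipped``.
    """
    valid = (pair.unfiltered > 0) & (pair.filtered > 0)
    t = np.zeros(pair.unfiltered.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, pair.unfiltered / pair.filtered, 1.0)
    t = pair.lam_inel * np.log(ratio)
    clipped = valid & (t < 0)
    t = np.where(valid, np.clip(t, 0.0, None), 0.0)
    return ThicknessMap(t, valid, clipped, pair.pixel_size_nm)


def detect_holes(em_image, expected_radius_px: float | None = None,
                 radius_tol: float = 0.4, min_circularity: float = 0.7):
    """Detect the bright circular foil holes in a low-mag EM image.

    Bright regions (holes transmit more signal than the foil) are
    thresholded with Otsu's criterion, labelled, and kept when circular
    enough and, if ``expected_radius_px`` is given, within
    ``radius_tol`` of the configured hole radius. Holes cut by the image
    border are excluded as incomplete. Deterministic; returns a list of
    ``(center_row, center_col, radius_px)``.
    """
    img = np.asarray(em_image, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("featureless image: no holes found")
        return []
    thr = filters.threshold_otsu(img)
    bright = img > thr
    # guard against an inverted threshold (foil brighter than holes)
    if bright.mean() > 0.5:
        bright = ~bright
    labels = measure.label(bright, connectivity=1)
    h, w = img.shape
    holes = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue  # incomplete hole at the border
        radius = np.sqrt(region.area / np.pi)
        if region.area < 4:
            continue
        circ = region.area / (np.pi * (max(r1 - r0, c1 - c0) / 2.0) ** 2)
        if circ < min_circularity:
            continue
        if expected_radius_px is not None:
            if abs(radius - expected_radius_px) > radius_tol * expected_radius_px:
                continue
        cy, cx = region.centroid
        holes.append((float(cy), float(cx), float(radius)))
    if not holes:
        warnings.warn("no holes found")
    holes.sort(key=lambda t: (t[0], t[1]))
    return holes


def square_summary(tmap: ThicknessMap, holes, square_id: int = 0,
                   n_holes: int = 10, seed: int = 0,
                   erode_px: int = 2) -> SquareSummary:
    """Representative grid-square thickness from randomly sampled holes.

    ``n_holes`` holes are drawn without replacement under the seed; each
    contributes the mean thickness over its interior (disc eroded by
    ``erode_px``). The summary is the mean and SD of those hole means.
    Fewer detected holes than requested falls back to all of them with a
    warning.
    """
    holes = list(holes)
    if not holes:
        raise ValueError("no holes to summarise")
    rng = np.random.default_rng([seed, 61])
    if len(holes) < n_holes:
        warnings.warn(f"only {len(holes)} holes available (< {n_holes}); using all")
        chosen = holes
    else:
        idx = rng.choice(len(holes), size=n_holes, replace=False)
        chosen = [holes[i] for i in sorted(idx)]
    yy, xx = np.mgrid[0:tmap.t_nm.shape[0], 0:tmap.t_nm.shape[1]]
    means = []
    for cy, cx, radius in chosen:
        r_in = max(radius - erode_px, 1.0)
        disc = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_in**2) & tmap.valid
        if not disc.any():
            continue
        means.append(float(tmap.t_nm[disc].mean()))
    means = np.asarray(means)
    sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    return SquareSummary(square_id, means, float(means.mean()), sd)
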