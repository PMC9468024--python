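"""Grid rotation estimation via the radon transform, and deskewing.

Projections of a grid image are sharpest (largest variance along the
detector axis) when the projection direction runs along the grid bars.
Scanning projection angles and maximising that sharpness recovers the
in-plane rotation up to the mesh's 90-degree symmetry; the estimate is
folded into [-45, 45). A coarse 1-degree pass followed by a fine pass at
the requested resolution keeps the transform quick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import radon, rotate, resize

from .synth import Interferogram

__all__ = ["GridAngle", "estimate_grid_angle", "rotate_to_axis",
           "map_point_to_original"]


@dataclass
class GridAngle:
    """Estimated grid rotation with its angular score profile."""

    angle_deg: float             # in [-45, 45)
    angles: np.ndarray           # candidate angles of the fine pass
    scores: np.ndarray           # projection-sharpness per candidate
    confident: bool = True


def _as_gray(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, Interferogram) else np.asarray(image, float)
    return arr.mean(axis=-1) if arr.ndim == 3 else arr


def _prepare(gray: np.ndarray, max_dim: int) -> np.ndarray:
    """Pad to square with a background fill, downsample for speed."""
    h, w = gray.shape
    fill = float(np.median(gray))
    side = max(h, w)
    sq = np.full((side, side), fill)
    r0, c0 = (side - h) // 2, (side - w) // 2
    sq[r0:r0 + h, c0:c0 + w] = gray
    if side > max_dim:
        sq = resize(sq, (max_dim, max_dim), order=1, anti_aliasing=True)
    return sq - sq.mean()


def _sharpness(image: np.ndarray, angles: np.ndarray) -> np.ndarray:
    sino = radon(image, theta=angles, circle=False)
    return sino.var(axis=0)


def _fold(angle: float) -> float:
    """Fold an angle into [-45, 45) using the grid's 90-degree symmetry."""
    return ((angle + 45.0) % 90.0) - 45.0


def estimate_grid_angle(image, angular_resolution: float = 0.25,
                        max_dim: int = 384) -> GridAngle:
    """Estimate the grid's in-plane rotation in degrees within [-45, 45).

    Ties break toward the smaller absolute angle. A featureless image
    (flat score profile) returns angle 0 with ``confident=False``.
    """
    if angular_resolution <= 0:
        raise ValueError("angular_resolution must be positive")
    gray = _prepare(_as_gray(image), max_dim)

    coarse_angles = np.arange(0.0, 90.0, 1.0)
    if np.ptp(gray) < 1e-6:  # flat image: no projections to sharpen
        return GridAngle(0.0, coarse_angles, np.zeros_like(coarse_angles),
                         confident=False)
    coarse = _sharpness(gray, coarse_angles)
    if coarse.max() < 1.05 * np.median(coarse) or coarse.max() <= 0:
        return GridAngle(0.0, coarse_angles, coarse, confident=False)
    best = coarse_angles[int(np.argmax(coarse))]

    fine_angles = np.arange(best - 1.5, best + 1.5 + angular_resolution / 2,
                            angular_resolution)
    fine = _sharpness(gray, fine_angles)
    # radon's theta runs clockwise relative to the image-axes convention
    # used here (row-major, angles counter-clockwise positive), hence -a
    folded = np.array([_fold(-a) for a in fine_angles])
    order = np.lexsort((np.abs(folded), -fine))  # max score, then small |angle|
    angle = float(folded[order[0]])
    return GridAngle(angle, fine_angles, fine, confident=True)


def rotate_to_axis(image, angle_deg: float):
    """Rotate an image by ``-angle_deg`` about its centre to axis-align the grid.

    Bilinear interpolation; the canvas grows to contain the whole rotated
    frame; new pixels take a background estimate (90th intensity
    percentile — the bright grid bars). Returns the same type as given.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    arr = image.pixels if isinstance(image, Interferogram) else np.asarray(image, float)
    if angle_deg == 0.0:
        rotated = arr.copy()
    else:
        fill = float(np.percentile(arr, 90))
        rotated = rotate(arr, angle_deg, resize=True, order=1, cval=fill,
                         mode="constant")
        rotated = np.clip(rotated, 0.0, 1.0)
    if isinstance(image, Interferogram):
        meta = dict(image.meta, deskewed_by_deg=float(angle_deg),
                    original_shape=arr.shape[:2])
        return Interferogram(rotated, image.pixel_size_um, image.magnification, meta)
    return rotated


def map_point_to_original(point, angle_deg: float, original_shape,
                          rotated_shape) -> tuple[float, float]:
    """Map a (row, col) point in the deskewed frame back to the original image.

    Inverse of :func:`rotate_to_axis` for coordinates: both frames share
    their centre, and deskewing rotated the content by ``-angle_deg``.
    """
    r, c = point
    hr, wr = rotated_shape[:2]
    ho, wo = original_shape[:2]
    dy, dx = r - (hr - 1) / 2.0, c - (wr - 1) / 2.0
    th = np.deg2rad(-angle_deg)
    # undo the -angle rotation: rotate the offset by +(-angle) image sense
    dyo = np.cos(th) * dy - np.sin(th) * dx
    dxo = np.sin(th) * dy + np.cos(th) * dx
    return (dyo + (ho - 1) / 2.0, dxo + (wo - 1) / 2.0)
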