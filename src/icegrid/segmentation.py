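"""Grid-square ("tile") versus background segmentation of interferograms.

Two interchangeable paths produce the same binary tile mask:

* a deterministic classical detector (default): the metal grid bars are
  the brightest, most colour-neutral structure in a reflected-light
  interferogram, so thresholding the channel-mean image separates bars
  (plus any empty field) from the film-filled squares;
* a trainable pixel classifier (a small MLP over local intensity/texture
  features) trained with the SGD recipe shared with the tile classifier.

Post-processing follows screening practice: fill holes inside detected
squares, drop asymmetric or tiny components, keep but flag squares that
touch the image border.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, filters

from .sgd import TrainSchedule, MLP
from .synth import Interferogram

__all__ = [
    "SegTrainConfig",
    "TileDetection",
    "segment_tiles",
    "postprocess_mask",
    "augment",
    "train_segmenter",
    "pixel_accuracy",
    "PixelSegmenter",
]


@dataclass
class SegTrainConfig(TrainSchedule):
    """Training configuration of the learned segmentation path."""

    pixels_per_image: int = 20000
    hidden: tuple = (16,)
    epochs: int = 24


@dataclass
class TileDetection:
    """One detected grid square."""

    tile_id: int
    bbox: tuple          # (row0, col0, row1, col1), half-open
    mask: np.ndarray     # bool raster of the full image shape
    area_px: int
    aspect_ratio: float  # max side / min side, >= 1
    touches_border: bool


def _as_array(image) -> np.ndarray:
    if isinstance(image, Interferogram):
        return image.pixels
    return np.asarray(image, dtype=float)


def _gray(image) -> np.ndarray:
    arr = _as_array(image)
    return arr.mean(axis=-1) if arr.ndim == 3 else arr


def segment_tiles(image, model=None, threshold: float = 0.90) -> np.ndarray:
    """Binary tile mask (tile=1, background=0) of an interferogram.

    With ``model=None`` the classical path runs: pixels darker than
    ``threshold`` on the channel mean are tile, a 3x3 median filter
    removes shot noise, and components touching no dark neighbourhood are
    left to :func:`postprocess_mask`. With a trained
    :class:`PixelSegmenter` the learned path runs instead; both are
    deterministic.
    """
    gray = _gray(image)
    if gray.ndim != 2:
        raise ValueError("expected a single RGB or grayscale raster")
    if isinstance(image, Interferogram):
        from .synth import GridSpec
        if min(gray.shape) * image.pixel_size_um < GridSpec().pitch_um:
            raise ValueError("image smaller than one grid pitch; "
                             "cannot contain a full grid square")
    if model is not None:
        return model.predict_mask(_as_array(image))
    if threshold is None:
        threshold = float(filters.threshold_otsu(gray))
    mask = gray < threshold
    mask = ndi.median_filter(mask.astype(np.uint8), size=3)
    return mask.astype(np.uint8)


def postprocess_mask(mask, max_aspect: float = 1.5,
                     min_area: float | None = None) -> list[TileDetection]:
    """Connected components of a tile mask, cleaned the standard way.

    Holes inside each component are filled, components with bounding-box
    aspect ratio above ``max_aspect`` or area below ``min_area`` are
    removed, and the survivors are returned sorted row-major by box
    origin. ``min_area=None`` defaults to 25% of the median component
    area. Components use 4-connectivity so diagonal bar gaps do not merge
    neighbouring squares.
    """
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask, connectivity=1)
    h, w = mask.shape
    comps = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        filled = ndi.binary_fill_holes(region.image)
        comp_mask = np.zeros((h, w), dtype=bool)
        comp_mask[r0:r1, c0:c1] = filled
        area = int(filled.sum())
        sides = sorted([r1 - r0, c1 - c0])
        aspect = sides[1] / sides[0] if sides[0] > 0 else np.inf
        border = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        comps.append(((r0, c0, r1, c1), comp_mask, area, aspect, border))

    if not comps:
        return []
    if min_area is None:
        min_area = 0.25 * float(np.median([c[2] for c in comps]))
    kept = [c for c in comps
            if c[3] <= max_aspect or c[4]]  # border squares are clipped, keep
    kept = [c for c in kept if c[2] >= min_area]
    kept.sort(key=lambda c: (c[0][0], c[0][1]))
    return [TileDetection(i, bbox, m, area, aspect, border)
            for i, (bbox, m, area, aspect, border) in enumerate(kept)]


def augment(image, mask, seed: int = 0, min_crop: float = 0.25,
            max_retries: int = 20) -> list[tuple[np.ndarray, np.ndarray]]:
    """Four extra labelled copies of an image/mask pair.

    Two copies rotated by random angles and two random crops of random
    size and position (emulating other magnifications and viewpoints);
    masks undergo exactly the same transform. Deterministic per seed.
    """
    from skimage.transform import rotate

    img = _as_array(image)
    msk = np.asarray(mask)
    if img.shape[:2] != msk.shape:
        raise ValueError("image and mask shapes disagree")
    rng = np.random.default_rng([seed, 31])
    out = []
    for _ in range(2):
        angle = float(rng.uniform(-180.0, 180.0))
        fill = float(np.percentile(img, 90))
        ri = rotate(img, angle, resize=True, order=1, cval=fill, mode="constant")
        rm = rotate(msk.astype(float), angle, resize=True, order=0, cval=0.0,
                    mode="constant")
        out.append((ri, (rm > 0.5).astype(msk.dtype)))
    h, w = msk.shape
    for _ in range(2):
        for attempt in range(max_retries):
            fh = rng.uniform(min_crop, 0.9)
            fw = rng.uniform(min_crop, 0.9)
            ch, cw = int(fh * h), int(fw * w)
            if ch >= 8 and cw >= 8:
                r0 = int(rng.integers(0, h - ch + 1))
                c0 = int(rng.integers(0, w - cw + 1))
                out.append((img[r0:r0 + ch, c0:c0 + cw].copy(),
                            msk[r0:r0 + ch, c0:c0 + cw].copy()))
                break
        else:
            raise RuntimeError("could not draw a crop above the minimum size")
    return out


def pixel_accuracy(predicted, truth) -> float:
    """Fraction of pixels on which two binary masks agree."""
    p = np.asarray(predicted).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean(p == t))


# ---------------------------------------------------------------------------
# learned path

def _pixel_features(img: np.ndarray) -> np.ndarray:
    """Per-pixel features: raw channels, local mean/SD, gradient magnitude."""
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    feats = [img[..., c] for c in range(3)]
    gray = img.mean(axis=-1)
    smooth = ndi.gaussian_filter(gray, 2.0)
    sq = ndi.gaussian_filter(gray**2, 2.0)
    local_sd = np.sqrt(np.clip(sq - smooth**2, 0.0, None))
    gx = ndi.sobel(gray, axis=0)
    gy = ndi.sobel(gray, axis=1)
    feats += [smooth, local_sd, np.hypot(gx, gy)]
    return np.stack(feats, axis=-1)


class PixelSegmenter:
    """Learned tile/background pixel classifier (features + small MLP)."""

    def __init__(self, model: MLP, mu: np.ndarray, sigma: np.ndarray):
        self.model = model
        self.mu = mu
        self.sigma = sigma

    def predict_mask(self, image) -> np.ndarray:
        F = _pixel_features(_as_array(image))
        X = (F.reshape(-1, F.shape[-1]) - self.mu) / self.sigma
        pred = self.model.predict(X).reshape(F.shape[:2])
        return pred.astype(np.uint8)

    def save(self, path) -> None:
        self.model.save(path)
        with np.load(path) as d:
            arrays = dict(d)
        arrays["mu"], arrays["sigma"] = self.mu, self.sigma
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "PixelSegmenter":
        model = MLP.load(path)
        with np.load(path) as d:
            mu, sigma = d["mu"], d["sigma"]
        return cls(model, mu, sigma)


def train_segmenter(dataset, config: SegTrainConfig | None = None):
    """Train the learned segmentation path on (image, mask) pairs.

    ``dataset`` is a sequence of ``(Interferogram|ndarray, mask)`` pairs
    (at least 2). A seeded subsample of pixels per image forms the
    training set; the last image is held out for the validation trace.
    Returns ``(PixelSegmenter, trace)`` with one trace entry per
    validation cadence.
    """
    config = config or SegTrainConfig()
    pairs = list(dataset)
    if len(pairs) == 0:
        raise ValueError("empty dataset")
    if len(pairs) < 2:
        raise ValueError("need at least 2 images to train the segmenter")
    rng = np.random.default_rng([config.seed, 41])
    Xs, ys = [], []
    for img, mask in pairs:
        F = _pixel_features(_as_array(img))
        X = F.reshape(-1, F.shape[-1])
        y = np.asarray(mask).reshape(-1).astype(int)
        take = min(config.pixels_per_image, len(X))
        idx = rng.choice(len(X), size=take, replace=False)
        Xs.append(X[idx])
        ys.append(y[idx])
    X_val, y_val = Xs.pop(), ys.pop()
    if not Xs:  # two images: train on the first, validate on the second
        Xs, ys = [X_val], [y_val]
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0) + 1e-9
    Xn = (X - mu) / sigma
    Xv = (X_val - mu) / sigma
    model = MLP(X.shape[1], 2, hidden=tuple(config.hidden), seed=config.seed)
    trace = model.fit(Xn, y, config, Xv, y_val)
    return PixelSegmenter(model, mu, sigma), trace


def detections_to_json(detections: list[TileDetection]) -> str:
    """Serialise detections (without pixel masks) to JSON."""
    return json.dumps([
        {"id": d.tile_id, "bbox": list(d.bbox), "area_px": d.area_px,
         "aspect_ratio": round(d.aspect_ratio, 4),
         "touches_border": d.touches_border}
        for d in detections], indent=1)
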