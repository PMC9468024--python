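"""Five-class ice-quality classification of detected grid squares.

Each grid square is classified as a whole (not per foil hole) into:

    0 bad       - defects: holes, scratches, dust, ice particles
    1 too thin  - film too thin to hold the particles
    2 optimal   - thickness suited to typical single-particle samples
    3 thicker   - likely too thick, may contain usable holes
    4 too thick - droplets / contrast-destroying ice

The classifier is a compact model trained from scratch on synthetic
tiles: interpretable image features (colour block means, channel
statistics, darkness and fringe-texture measures) feeding a small
softmax network trained with momentum SGD, cross-entropy loss and the
piecewise learning schedule. The output is a full probability vector;
confidence is its maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .sgd import TrainSchedule, MLP
from .synth import Interferogram

__all__ = [
    "CLASS_NAMES",
    "CLASS_PALETTE",
    "IceClass",
    "ClassResult",
    "ClfTrainConfig",
    "TileClassifier",
    "extract_tile_crops",
    "tile_features",
    "classify_tile",
    "classify_tiles",
    "train_classifier",
    "confidence_histograms",
    "histograms_to_csv",
]

CLASS_NAMES = ("bad", "too thin", "optimal", "thicker", "too thick")

#: display palette: 0 red, 1 white, 2 green, 3 bright green, 4 orange
CLASS_PALETTE = (
    (220, 40, 40),
    (245, 245, 245),
    (0, 160, 70),
    (130, 230, 90),
    (255, 150, 0),
)


@dataclass(frozen=True)
class IceClass:
    index: int

    def __post_init__(self):
        if not 0 <= self.index <= 4:
            raise ValueError("class index must be 0-4")

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.index]

    @property
    def color(self) -> tuple:
        return CLASS_PALETTE[self.index]


@dataclass
class ClassResult:
    """Classification of one tile: class, probability vector, confidence."""

    tile_id: int
    ice_class: IceClass
    probabilities: np.ndarray
    confidence: float

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (5,) or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be a 5-vector summing to 1")
        if int(np.argmax(p)) != self.ice_class.index:
            raise ValueError("predicted class must be the argmax probability")


@dataclass
class ClfTrainConfig(TrainSchedule):
    """Training configuration of the tile classifier."""

    crop_size: int = 128
    split: float = 0.2      # validation fraction of the stratified split
    hidden: tuple = (64, 32)
    epochs: int = 48
    batch_size: int = 16
    min_tile_px: int = 8
    n_members: int = 5   # seeded ensemble members; probabilities averaged

    def __post_init__(self):
        super().__post_init__()
        if not 0 < self.split < 1:
            raise ValueError("split fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# crops and features

def extract_tile_crops(image, detections, size: int = 128,
                       inset_frac: float = 0.08, min_px: int = 8):
    """Fixed-size normalised crops of detected tiles, in detection order.

    Each bounding box is shrunk by ``inset_frac`` per side (trimming bar
    remnants), resampled to ``size x size`` and clipped to [0, 1].
    Detections smaller than ``min_px`` on a side are skipped with a
    warning. Returns ``(crops, kept_detections)``.
    """
    arr = image.pixels if isinstance(image, Interferogram) else np.asarray(image, float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    crops, kept = [], []
    for det in detections:
        r0, c0, r1, c1 = det.bbox
        if min(r1 - r0, c1 - c0) < min_px:
            warnings.warn(f"tile {det.tile_id}: bbox below {min_px} px, skipped")
            continue
        dr = int(round((r1 - r0) * inset_frac))
        dc = int(round((c1 - c0) * inset_frac))
        sub = arr[r0 + dr:r1 - dr, c0 + dc:c1 - dc]
        crop = resize(sub, (size, size), order=1, anti_aliasing=True)
        crops.append(np.clip(crop, 0.0, 1.0).astype(np.float32))
        kept.append(det)
    if not crops:
        return np.zeros((0, size, size, 3)), []
    return np.stack(crops), kept


def tiles_from_dataset(items, size: int = 128, inset_frac: float = 0.08,
                       include_border: bool = False):
    """Labelled crops from ``(Interferogram, GroundTruth)`` dataset items.

    Cuts every (by default non-border) square's ground-truth bounding box
    out of its image and resamples it, returning ``(crops, labels)`` —
    the labelled-tile corpus the classifier trains on.
    """
    from .segmentation import TileDetection

    crops, labels = [], []
    for intf, truth in items:
        dets, labs = [], []
        for rec in truth.squares:
            if rec["border"] and not include_border:
                continue
            dets.append(TileDetection(rec["square_id"], tuple(rec["bbox"]),
                                      None, rec["area_px"], 1.0, rec["border"]))
            labs.append(rec["label"])
        cs, kept = extract_tile_crops(intf, dets, size=size,
                                      inset_frac=inset_frac)
        kept_ids = {d.tile_id for d in kept}
        labs = [l for d, l in zip(dets, labs) if d.tile_id in kept_ids]
        if len(cs):
            crops.append(cs)
            labels.extend(labs)
    if not crops:
        return np.zeros((0, size, size, 3)), np.zeros(0, dtype=int)
    return np.concatenate(crops), np.asarray(labels, dtype=int)


def tile_features(crops: np.ndarray) -> np.ndarray:
    """Feature matrix for a stack of (N, S, S, 3) tile crops.

    Colour encodes thickness through the interference model, so the
    features are colour block means (6x6 grid), per-channel order
    statistics, a dark-pixel fraction (defects, punched holes), gradient
    energy (droplet fringes) and centre-minus-rim contrast (puddles).
    """
    crops = np.asarray(crops, dtype=float)
    if crops.ndim == 3:
        crops = crops[None]
    n, s = crops.shape[0], crops.shape[1]
    feats = []
    gray = crops.mean(axis=-1)
    # 6x6 block colour means and block texture (per-block gray SD)
    nb = 6
    edges = np.linspace(0, s, nb + 1).astype(int)
    blocks = np.empty((n, nb, nb, 3))
    bstd = np.empty((n, nb, nb))
    for i in range(nb):
        for j in range(nb):
            sub = crops[:, edges[i]:edges[i + 1], edges[j]:edges[j + 1]]
            blocks[:, i, j] = sub.mean(axis=(1, 2))
            bstd[:, i, j] = sub.mean(axis=-1).std(axis=(1, 2))
    feats.append(blocks.reshape(n, -1))
    feats.append(bstd.reshape(n, -1))
    flat = crops.reshape(n, -1, 3)
    qs = np.percentile(flat, [1, 5, 10, 50, 90, 99], axis=1)  # (6, n, 3)
    feats.append(np.moveaxis(qs, 0, 1).reshape(n, -1))
    feats.append(flat.mean(axis=1))
    feats.append(flat.std(axis=1))
    g = gray.reshape(n, -1)
    for thr in (0.04, 0.10):  # dark pixels: punched holes, scratches, dust
        feats.append((g < thr).mean(axis=1, keepdims=True))
    med = np.median(flat, axis=1)[:, None, :]
    dev = np.abs(flat - med).max(axis=-1)
    for thr in (0.10, 0.20):  # colour outliers relative to the crop median
        feats.append((dev > thr).mean(axis=1, keepdims=True))
    grads = np.empty((n, 2))
    for k in range(n):  # fringe texture of thick-ice droplets
        gx = ndi.sobel(gray[k], axis=0)
        gy = ndi.sobel(gray[k], axis=1)
        gm = np.hypot(gx, gy)
        grads[k] = (gm.mean(), np.percentile(gm, 99))
    feats.append(grads)
    third = s // 3
    centre = crops[:, third:-third, third:-third].mean(axis=(1, 2))
    rim = (flat.sum(axis=1) - crops[:, third:-third, third:-third]
           .reshape(n, -1, 3).sum(axis=1))
    rim = rim / (flat.shape[1] - (s - 2 * third) ** 2)
    feats.append(centre - rim)  # centre-weighted puddles
    return np.concatenate(feats, axis=1)


# ---------------------------------------------------------------------------
# the classifier

class TileClassifier:
    """Feature scaler plus a small ensemble of softmax MLPs.

    Member probability vectors are averaged, which damps the
    initialisation/shuffling variance of individual members.
    Serialisable to a single versioned .npz file.
    """

    def __init__(self, models, mu: np.ndarray, sigma: np.ndarray,
                 crop_size: int = 128):
        self.models = [models] if isinstance(models, MLP) else list(models)
        self.mu = mu
        self.sigma = sigma
        self.crop_size = int(crop_size)

    def predict_proba(self, crops) -> np.ndarray:
        crops = np.asarray(crops, dtype=float)
        if crops.ndim == 3:
            crops = crops[None]
        if crops.shape[1] != self.crop_size:
            raise ValueError(f"model expects {self.crop_size}px crops, "
                             f"got {crops.shape[1]}")
        X = (tile_features(crops) - self.mu) / self.sigma
        p = np.mean([m.predict_proba(X) for m in self.models], axis=0)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, crops) -> np.ndarray:
        return self.predict_proba(crops).argmax(axis=1)

    def save(self, path) -> None:
        arrays = {"clf_version": np.array([2]),
                  "n_members": np.array([len(self.models)]),
                  "mu": self.mu, "sigma": self.sigma,
                  "crop_size": np.array([self.crop_size])}
        import io
        for i, m in enumerate(self.models):
            buf = io.BytesIO()
            m.save(buf)
            buf.seek(0)
            with np.load(buf) as d:
                for key, val in d.items():
                    arrays[f"m{i}_{key}"] = val
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TileClassifier":
        import io
        with np.load(path) as d:
            if int(d["clf_version"][0]) != 2:
                raise ValueError("unsupported classifier file version")
            models = []
            for i in range(int(d["n_members"][0])):
                buf = io.BytesIO()
                member = {k[len(f"m{i}_"):]: v for k, v in d.items()
                          if k.startswith(f"m{i}_")}
                np.savez(buf, **member)
                buf.seek(0)
                models.append(MLP.load(buf))
            return cls(models, d["mu"], d["sigma"], int(d["crop_size"][0]))


def classify_tile(crop, model: TileClassifier, tile_id: int = 0) -> ClassResult:
    """Classify one crop; returns the full probability vector and confidence."""
    probs = model.predict_proba(crop)[0]
    k = int(np.argmax(probs))
    return ClassResult(tile_id, IceClass(k), probs, float(probs[k]))


def classify_tiles(crops, detections, model: TileClassifier) -> list[ClassResult]:
    """Classify a stack of crops, carrying over detection ids."""
    if len(crops) == 0:
        return []
    probs = model.predict_proba(crops)
    out = []
    for det, p in zip(detections, probs):
        k = int(np.argmax(p))
        out.append(ClassResult(det.tile_id, IceClass(k), p, float(p[k])))
    return out


def train_classifier(crops, labels, config: ClfTrainConfig | None = None):
    """Train the tile classifier on labelled crops.

    A stratified ``1 - split`` / ``split`` train/validation split is
    drawn per class under the config seed. Returns
    ``(TileClassifier, report)`` where the report carries the validation
    accuracy, per-class accuracies and the cadenced accuracy trace.
    Raises if any of the five classes is missing from the data.
    """
    config = config or ClfTrainConfig()
    crops = np.asarray(crops, dtype=float)
    labels = np.asarray(labels, dtype=int)
    present = set(np.unique(labels).tolist())
    missing = set(range(5)) - present
    if len(labels) >= 5 and missing:
        raise ValueError(f"classes missing from training data: {sorted(missing)}")
    if len(labels) < 2 or len(present) < 2:
        raise ValueError("need at least 2 examples of at least 2 classes")

    rng = np.random.default_rng([config.seed, 51])
    val_idx = []
    for k in sorted(present):
        idx = np.flatnonzero(labels == k)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(config.split * len(idx)))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
    val_mask = np.zeros(len(labels), dtype=bool)
    val_mask[val_idx] = True

    X = tile_features(crops)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0) + 1e-9
    Xn = (X - mu) / sigma
    n_classes = 5
    models, trace = [], None
    for m in range(max(1, config.n_members)):
        member_seed = config.seed * 1000 + m
        schedule = replace(config, seed=member_seed)
        model = MLP(Xn.shape[1], n_classes, hidden=tuple(config.hidden),
                    seed=member_seed)
        t = model.fit(Xn[~val_mask], labels[~val_mask], schedule,
                      Xn[val_mask], labels[val_mask])
        trace = trace or t  # first member's cadenced accuracy trace
        models.append(model)

    clf = TileClassifier(models, mu, sigma, crop_size=crops.shape[1])

    def _ens_pred(Z):
        p = np.mean([m.predict_proba(Z) for m in models], axis=0)
        return p.argmax(axis=1)

    if val_mask.any():
        pred = _ens_pred(Xn[val_mask])
        yv = labels[val_mask]
        val_acc = float(np.mean(pred == yv))
        per_class = {int(k): float(np.mean(pred[yv == k] == k))
                     for k in sorted(present) if np.any(yv == k)}
    else:
        pred = _ens_pred(Xn)
        val_acc = float(np.mean(pred == labels))
        per_class = {}
    report = {"validation_accuracy": val_acc, "per_class_accuracy": per_class,
              "trace": trace, "n_train": int((~val_mask).sum()),
              "n_val": int(val_mask.sum())}
    return clf, report


def confidence_histograms(results, bins: int = 20):
    """Per-class histogram of the probability assigned to the chosen class.

    Returns ``{class_index: (counts, bin_edges)}`` over [0, 1]; counts of
    each class sum to the number of results assigned to it. An empty
    result list gives empty (all-zero) histograms.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = {}
    for k in range(5):
        conf = [r.confidence for r in results if r.ice_class.index == k]
        counts, _ = np.histogram(conf, bins=edges) if conf else (
            np.zeros(bins, dtype=int), edges)
        out[k] = (counts, edges)
    return out


def histograms_to_csv(histograms, path) -> None:
    """Write per-class confidence histograms as one CSV table."""
    import pandas as pd

    rows = []
    for k, (counts, edges) in histograms.items():
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append({"class": k, "name": CLASS_NAMES[k],
                         "bin_low": round(float(lo), 6),
                         "bin_high": round(float(hi), 6), "count": int(c)})
    pd.DataFrame(rows).to_csv(path, index=False)
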