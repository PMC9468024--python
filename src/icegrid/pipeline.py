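"""End-to-end grid analysis and the watch-folder batch service.

One image passes through: rotation estimate (radon) -> deskew ->
tile/background segmentation -> component post-processing -> per-tile
five-class classification -> annotated overlay + JSON report. The watch
mode polls a raw-image folder and writes the analysed outputs to a
second folder, mirroring unattended operation next to the microscope.

Reports are written atomically (temp file + rename) and are byte-stable:
the same image, configuration, seed and weights reproduce an identical
report.
"""

from __future__ import annotations

import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import yaml
from PIL import Image, ImageDraw

from . import __version__ as _pkg_version
from .synth import Interferogram
from .orientation import estimate_grid_angle, rotate_to_axis
from .segmentation import segment_tiles, postprocess_mask, PixelSegmenter
from .classification import (TileClassifier, extract_tile_crops,
                             classify_tiles, CLASS_NAMES, CLASS_PALETTE)

__all__ = ["PipelineConfig", "AnalysisReport", "analyze_image",
           "render_overlay", "watch"]

log = logging.getLogger("icegrid")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass
class PipelineConfig:
    """Configuration of the analysis pipeline.

    Model fields accept either a path to a serialised model or an
    in-memory object; the classical segmentation path needs no model.
    """

    classifier: object = None          # TileClassifier or path (required)
    segmenter: object = None           # PixelSegmenter or path (learned path)
    segmentation_path: str = "classical"   # "classical" | "learned"
    seg_threshold: float = 0.90
    max_aspect: float = 1.5
    min_area: float | None = None
    crop_size: int = 128
    angular_resolution: float = 0.25
    overlay_alpha: float = 0.45
    pixel_size_um: float = 0.65
    magnification: int = 10
    poll_interval_s: float = 2.0
    settle_s: float = 0.5
    process_existing: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.segmentation_path not in ("classical", "learned"):
            raise ValueError("segmentation_path must be 'classical' or 'learned'")
        if self.segmentation_path == "learned" and self.segmenter is None:
            raise ValueError("learned segmentation path requires a segmenter")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def resolved_classifier(self) -> TileClassifier:
        if isinstance(self.classifier, TileClassifier):
            return self.classifier
        if self.classifier is None:
            raise ValueError("pipeline needs a trained tile classifier")
        p = Path(self.classifier)
        if not p.exists():
            raise FileNotFoundError(f"classifier model not found: {p}")
        return TileClassifier.load(p)

    def resolved_segmenter(self):
        if self.segmentation_path != "learned":
            return None
        if isinstance(self.segmenter, PixelSegmenter):
            return self.segmenter
        p = Path(self.segmenter)
        if not p.exists():
            raise FileNotFoundError(f"segmenter model not found: {p}")
        return PixelSegmenter.load(p)

    def snapshot(self) -> dict:
        d = asdict(self)
        for key in ("classifier", "segmenter"):
            v = d[key]
            d[key] = str(v) if isinstance(v, (str, Path)) else (
                None if v is None else f"<in-memory {type(v).__name__}>")
        return d


@dataclass
class AnalysisReport:
    """Per-image analysis result; serialises to a stable JSON document."""

    source: str
    angle_deg: float
    angle_confident: bool
    tiles: list            # per-tile dicts: id, bbox, class, name, confidence, probs
    deskewed_shape: tuple
    original_shape: tuple
    version: str = _pkg_version
    config: dict = field(default_factory=dict)
    timing_s: float | None = None   # wall clock; excluded from the JSON document

    def to_json(self) -> str:
        doc = {
            "source": self.source,
            "angle_deg": round(self.angle_deg, 4),
            "angle_confident": self.angle_confident,
            "original_shape": list(self.original_shape),
            "deskewed_shape": list(self.deskewed_shape),
            "tiles": self.tiles,
            "version": self.version,
            "config": self.config,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(d["source"], d["angle_deg"], d["angle_confident"], d["tiles"],
                   tuple(d["deskewed_shape"]), tuple(d["original_shape"]),
                   d["version"], d["config"])


def _flag_partial_tiles(detections, angle_deg, original_shape, deskewed_shape):
    """Mark detections that extend past the original image frame.

    Deskewing grows the canvas, so a square cut by the original image
    edge no longer touches the border of the rotated frame — but part of
    its crop is background fill. Mapping the bounding-box corners back to
    the original frame exposes these partial squares; they keep their
    detection but carry the border flag.
    """
    from .orientation import map_point_to_original

    h, w = original_shape[:2]
    for det in detections:
        r0, c0, r1, c1 = det.bbox
        for corner in ((r0, c0), (r0, c1 - 1), (r1 - 1, c0), (r1 - 1, c1 - 1)):
            orow, ocol = map_point_to_original(corner, angle_deg,
                                               original_shape, deskewed_shape)
            if not (0 <= orow <= h - 1 and 0 <= ocol <= w - 1):
                det.touches_border = True
                break
    return detections


def analyze_image(image, config: PipelineConfig):
    """Run the full pipeline on one image.

    ``image`` is a path, an ndarray or an :class:`Interferogram`. Returns
    ``(AnalysisReport, overlay)`` where the overlay is the deskewed image
    with semi-transparent class colours and confidences.
    """
    t0 = time.perf_counter()
    if isinstance(image, (str, Path)):
        source = str(image)
        intf = Interferogram.load(image, config.pixel_size_um, config.magnification)
    elif isinstance(image, Interferogram):
        source, intf = "<memory>", image
    else:
        source = "<memory>"
        intf = Interferogram(np.asarray(image, dtype=float),
                             config.pixel_size_um, config.magnification)

    clf = config.resolved_classifier()
    ga = estimate_grid_angle(intf, config.angular_resolution)
    deskewed = rotate_to_axis(intf, ga.angle_deg)
    mask = segment_tiles(deskewed, model=config.resolved_segmenter(),
                         threshold=config.seg_threshold)
    detections = postprocess_mask(mask, config.max_aspect, config.min_area)
    _flag_partial_tiles(detections, ga.angle_deg, intf.pixels.shape,
                        deskewed.pixels.shape)
    crops, kept = extract_tile_crops(deskewed, detections, size=config.crop_size)
    results = classify_tiles(crops, kept, clf)

    tiles = []
    for det, res in zip(kept, results):
        tiles.append({
            "id": det.tile_id,
            "bbox": list(det.bbox),
            "area_px": det.area_px,
            "touches_border": det.touches_border,
            "class": res.ice_class.index,
            "name": res.ice_class.name,
            "confidence": round(res.confidence, 4),
            "probabilities": [round(float(p), 6) for p in res.probabilities],
        })
    report = AnalysisReport(source, ga.angle_deg, ga.confident, tiles,
                            deskewed.pixels.shape[:2], intf.pixels.shape[:2],
                            config=config.snapshot())
    overlay = render_overlay(deskewed, kept, results,
                             alpha=config.overlay_alpha)
    report.timing_s = time.perf_counter() - t0
    return report, overlay


def harvest_tiles(items, config: PipelineConfig | None = None,
                  include_border: bool = False):
    """Detected, labelled tile crops from synthetic dataset items.

    Runs the front half of the pipeline (deskew -> segmentation ->
    post-processing -> crop extraction) on each ``(Interferogram,
    GroundTruth)`` pair and labels every detected tile by reading the
    ground-truth class at the tile centre mapped back to the original
    frame. This yields a labelled-tile corpus with exactly the crop
    statistics the classifier will see in production.

    Returns ``(crops, labels)``.
    """
    from .orientation import map_point_to_original

    config = config or PipelineConfig()
    crops_all, labels = [], []
    for intf, truth in items:
        ga = estimate_grid_angle(intf, config.angular_resolution)
        deskewed = rotate_to_axis(intf, ga.angle_deg)
        mask = segment_tiles(deskewed, model=config.resolved_segmenter(),
                             threshold=config.seg_threshold)
        detections = postprocess_mask(mask, config.max_aspect, config.min_area)
        _flag_partial_tiles(detections, ga.angle_deg, intf.pixels.shape,
                            deskewed.pixels.shape)
        crops, kept = extract_tile_crops(deskewed, detections,
                                         size=config.crop_size)
        h, w = truth.label_raster.shape
        for crop, det in zip(crops, kept):
            if det.touches_border and not include_border:
                continue
            r0, c0, r1, c1 = det.bbox
            orow, ocol = map_point_to_original(((r0 + r1) / 2, (c0 + c1) / 2),
                                               ga.angle_deg,
                                               truth.label_raster.shape,
                                               deskewed.pixels.shape)
            orow, ocol = int(round(orow)), int(round(ocol))
            if not (0 <= orow < h and 0 <= ocol < w):
                continue
            label = int(truth.label_raster[orow, ocol])
            if label < 0:
                continue
            crops_all.append(crop)
            labels.append(label)
    if not crops_all:
        return np.zeros((0, config.crop_size, config.crop_size, 3)), \
            np.zeros(0, dtype=int)
    return np.stack(crops_all), np.asarray(labels, dtype=int)


def benchmark_tile_corpus(seed: int, n_images: int = 120, chunk: int = 40,
                          magnification: int = 5,
                          angle_range=(-40.0, 40.0)):
    """The default labelled-tile benchmark corpus.

    Generates ``n_images`` synthetic grid images (in memory-bounded
    chunks) with rotations drawn from ``angle_range`` and harvests their
    detected tiles via :func:`harvest_tiles`. Returns ``(crops, labels)``
    as float32.
    """
    from .synth import make_dataset, GridSpec

    cfg = PipelineConfig(pixel_size_um=GridSpec().pixel_size(magnification),
                         magnification=magnification)
    crops, labels = [], []
    done, part = 0, 0
    while done < n_images:
        n = min(chunk, n_images - done)
        items, _ = make_dataset(n, magnification=magnification,
                                seed=seed * 1000 + part,
                                angle_range=angle_range)
        c, l = harvest_tiles(items, cfg)
        if len(l):
            crops.append(c.astype(np.float32))
            labels.append(l)
        done += n
        part += 1
    return np.concatenate(crops), np.concatenate(labels)


def render_overlay(image, detections, results, palette=CLASS_PALETTE,
                   alpha: float = 0.45) -> np.ndarray:
    """Annotated RGB overlay: class-coloured tiles plus confidence text.

    Each tile's mask is alpha-blended with its class colour and the
    confidence is printed to two decimals at the tile centre. Pixels
    outside tiles are untouched. Returns a uint8 (H, W, 3) array.
    """
    arr = image.pixels if isinstance(image, Interferogram) else np.asarray(image, float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    out = arr.copy()
    for det, res in zip(detections, results):
        color = np.asarray(palette[res.ice_class.index], dtype=float) / 255.0
        m = det.mask
        out[m] = (1 - alpha) * out[m] + alpha * color
    img8 = np.clip(np.round(out * 255), 0, 255).astype(np.uint8)
    pil = Image.fromarray(img8)
    draw = ImageDraw.Draw(pil)
    for det, res in zip(detections, results):
        r0, c0, r1, c1 = det.bbox
        cy, cx = (r0 + r1) / 2.0, (c0 + c1) / 2.0
        text = f"{res.confidence:.2f}"
        draw.text((cx, cy), text, fill=(20, 20, 20), anchor="mm")
    return np.asarray(pil)


def _atomic_write(path: Path, data: bytes) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "wb") as fh:
        fh.write(data)
    os.replace(tmp, path)


def _process_one(path: Path, out_dir: Path, config: PipelineConfig) -> bool:
    try:
        report, overlay = analyze_image(path, config)
    except Exception as exc:  # corrupt/unreadable image: skip, no partial output
        log.error("failed to analyse %s: %s", path, exc)
        return False
    stem = path.stem
    _atomic_write(out_dir / f"{stem}.report.json",
                  report.to_json().encode())
    import io
    buf = io.BytesIO()
    Image.fromarray(overlay).save(buf, format="PNG")
    _atomic_write(out_dir / f"{stem}.overlay.png", buf.getvalue())
    log.info("analysed %s: %d tiles in %.2fs", path.name, len(report.tiles),
             report.timing_s or 0.0)
    return True


def watch(raw_folder, out_folder, config: PipelineConfig,
          max_events: int | None = None, timeout_s: float | None = None,
          stop_flag=None) -> int:
    """Poll ``raw_folder`` and analyse each newly appearing image once.

    Outputs (overlay PNG + JSON report) land in ``out_folder``
    atomically. A file is reprocessed when its modification time changes
    (an overwrite counts as a new appearance event); partially written
    files are retried on the next poll because processing waits for the
    modification time to settle. Returns the number of images processed.

    ``max_events``/``timeout_s``/``stop_flag`` bound the loop for
    programmatic use; with all three unset the loop runs until
    interrupted (SIGINT exits cleanly).
    """
    raw = Path(raw_folder)
    out = Path(out_folder)
    if not raw.is_dir() or not out.is_dir():
        raise ValueError("both folders must exist")
    processed: dict[str, float] = {}
    if not config.process_existing:
        for p in sorted(raw.iterdir()):
            if p.suffix.lower() in IMAGE_SUFFIXES:
                processed[p.name] = p.stat().st_mtime
    count = 0
    start = time.monotonic()
    try:
        while True:
            for p in sorted(raw.iterdir()):
                if p.suffix.lower() not in IMAGE_SUFFIXES:
                    if p.name not in processed:
                        log.info("ignoring non-image file %s", p.name)
                        processed[p.name] = -1.0
                    continue
                mtime = p.stat().st_mtime
                if processed.get(p.name) == mtime:
                    continue
                if time.time() - mtime < config.settle_s:
                    continue  # still being written; retry next poll
                if _process_one(p, out, config):
                    count += 1
                processed[p.name] = mtime
                if max_events is not None and count >= max_events:
                    return count
            if max_events is not None and count >= max_events:
                return count
            if timeout_s is not None and time.monotonic() - start > timeout_s:
                return count
            if stop_flag is not None and stop_flag():
                return count
            time.sleep(config.poll_interval_s)
    except KeyboardInterrupt:
        log.info("watch interrupted; shutting down")
        return count
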