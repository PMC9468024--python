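"""Train the five-class tile classifier and analyse one grid image.

Harvests labelled tiles from a small synthetic dataset through the
detection pipeline, trains the classifier with the momentum-SGD recipe,
then runs the full analysis (deskew -> segment -> classify -> overlay)
on a fresh image.
"""

import imageio.v3 as iio

import icegrid as ig
from icegrid.pipeline import PipelineConfig, harvest_tiles, analyze_image
from icegrid.classification import train_classifier, ClfTrainConfig

# a small training corpus (increase n_images for production accuracy)
items, _ = ig.make_dataset(20, magnification=5, seed=1,
                           angle_range=(-40.0, 40.0))
base_cfg = PipelineConfig(pixel_size_um=1.30, magnification=5)
crops, labels = harvest_tiles(items, base_cfg)
print(f"harvested {len(labels)} labelled tiles")

clf, report = train_classifier(crops, labels, ClfTrainConfig(seed=0))
print(f"validation accuracy: {report['validation_accuracy']:.3f} "
      f"on {report['n_val']} held-out tiles")

# analyse a fresh image
test_items, _ = ig.make_dataset(1, magnification=5, seed=99,
                                angle_range=(-40.0, 40.0))
cfg = PipelineConfig(classifier=clf, pixel_size_um=1.30, magnification=5)
analysis, overlay = analyze_image(test_items[0][0], cfg)

print(f"estimated grid rotation: {analysis.angle_deg:.2f} deg")
print(f"{len(analysis.tiles)} grid squares detected:")
for t in analysis.tiles:
    print(f"  tile {t['id']:2d}: class {t['class']} ({t['name']:9s}) "
          f"confidence {t['confidence']:.2f}"
          + ("  [border]" if t['touches_border'] else ""))
iio.imwrite("example_overlay.png", overlay)
# The overlay colours each square by ice quality (red=bad, white=too
# thin, green=optimal, bright green=thicker, orange=too thick) and
# prints the classifier confidence at the square centre.
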