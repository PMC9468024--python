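"""Shared fixtures: synthetic benchmark datasets and a trained classifier.

The heavy fixtures are session-scoped so the tile corpus is harvested
and the classifier trained once for the whole suite.
"""

import numpy as np
import pytest

import icegrid as ig
from icegrid.classification import train_classifier, ClfTrainConfig
from icegrid.pipeline import PipelineConfig, harvest_tiles


def pipeline_config(**kw):
    kw.setdefault("pixel_size_um", 1.30)
    kw.setdefault("magnification", 5)
    return PipelineConfig(**kw)


@pytest.fixture(scope="session")
def benchmark_corpus():
    """>= 2000 labelled tiles harvested through the detection pipeline
    from 120 synthetic grid images (5x, random rotations, seeded)."""
    from icegrid.pipeline import benchmark_tile_corpus
    crops, labels = benchmark_tile_corpus(seed=1)
    assert len(labels) >= 2000
    return crops, labels


@pytest.fixture(scope="session")
def trained_classifier(benchmark_corpus):
    """Five-class tile classifier trained with the default SGD recipe."""
    crops, labels = benchmark_corpus
    clf, report = train_classifier(crops, labels, ClfTrainConfig(seed=0))
    return clf, report


@pytest.fixture(scope="session")
def small_dataset():
    """Four axis-aligned-ish images with ground truth, for cheap tests."""
    items, manifest = ig.make_dataset(4, magnification=5, seed=21,
                                      angle_range=(-3.0, 3.0))
    return items, manifest
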