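"""Five-class tile classification: crops, features, training, confidence."""

import warnings

import numpy as np
import pytest

import icegrid as ig
from icegrid.classification import (IceClass, ClassResult, ClfTrainConfig,
                                    extract_tile_crops, classify_tile,
                                    classify_tiles, train_classifier,
                                    confidence_histograms, tiles_from_dataset,
                                    CLASS_NAMES, CLASS_PALETTE, TileClassifier)
from icegrid.segmentation import TileDetection


def _det(tile_id, bbox, border=False):
    return TileDetection(tile_id, bbox, None, 1, 1.0, border)


class TestIceClass:
    def test_names_and_palette(self):
        assert [IceClass(k).name for k in range(5)] == list(CLASS_NAMES)
        assert IceClass(0).color == CLASS_PALETTE[0]
        with pytest.raises(ValueError):
            IceClass(5)

    def test_class_result_validates_distribution(self):
        with pytest.raises(ValueError):
            ClassResult(0, IceClass(2), np.array([0.2, 0.2, 0.2, 0.2, 0.1]), 0.2)
        with pytest.raises(ValueError):  # argmax disagrees with class
            ClassResult(0, IceClass(0), np.array([0.1, 0.6, 0.1, 0.1, 0.1]), 0.6)


class TestCrops:
    def test_crop_count_and_order(self, small_dataset):
        items, _ = small_dataset
        intf, truth = items[0]
        recs = [r for r in truth.squares if not r["border"]][:2]
        dets = [_det(i, tuple(r["bbox"])) for i, r in enumerate(recs)]
        crops, kept = extract_tile_crops(intf, dets, size=64)
        assert crops.shape == (2, 64, 64, 3)
        assert [d.tile_id for d in kept] == [0, 1]
        assert crops.min() >= 0 and crops.max() <= 1

    def test_centred_square_crop_matches_region(self, small_dataset):
        items, _ = small_dataset
        intf, truth = items[0]
        rec = next(r for r in truth.squares if not r["border"])
        r0, c0, r1, c1 = rec["bbox"]
        crops, _ = extract_tile_crops(intf, [_det(0, (r0, c0, r1, c1))],
                                      size=64, inset_frac=0.0)
        from skimage.transform import resize
        expected = resize(intf.pixels[r0:r1, c0:c1], (64, 64), order=1,
                          anti_aliasing=True)
        # crops are stored as float32
        assert np.abs(crops[0] - np.clip(expected, 0, 1)).max() < 1e-6

    def test_degenerate_detection_skipped_with_warning(self, small_dataset):
        items, _ = small_dataset
        intf, _ = items[0]
        with pytest.warns(UserWarning, match="below"):
            crops, kept = extract_tile_crops(intf, [_det(0, (5, 5, 6, 6))])
        assert len(crops) == 0 and kept == []

    def test_empty_detection_list_is_not_an_error(self, small_dataset):
        items, _ = small_dataset
        crops, kept = extract_tile_crops(items[0][0], [])
        assert crops.shape[0] == 0


class TestClassifier:
    def test_probabilities_are_distributions(self, trained_classifier,
                                             benchmark_corpus):
        clf, _ = trained_classifier
        crops, _ = benchmark_corpus
        probs = clf.predict_proba(crops[:32])
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_optimal_thickness_tiles_classified_class2(self, trained_classifier):
        """Uniform ~40 nm squares (the 'optimal' regime) come back class 2."""
        clf, _ = trained_classifier
        items, _ = ig.make_dataset(3, class_mix=(0, 0, 1, 0, 0),
                                   magnification=5, seed=555,
                                   angle_range=(-3, 3))
        crops, labels = tiles_from_dataset(items)
        assert len(crops) >= 20
        pred = clf.predict_proba(crops).argmax(axis=1)
        assert np.mean(pred == 2) >= 0.95

    def test_defect_tiles_classified_bad(self, trained_classifier):
        clf, _ = trained_classifier
        items, _ = ig.make_dataset(3, class_mix=(1, 0, 0, 0, 0),
                                   magnification=5, seed=556,
                                   angle_range=(-3, 3))
        crops, labels = tiles_from_dataset(items)
        pred = clf.predict_proba(crops).argmax(axis=1)
        assert np.mean(pred == 0) >= 0.9

    def test_memorises_one_example_per_class(self, benchmark_corpus):
        crops, labels = benchmark_corpus
        idx = [int(np.flatnonzero(labels == k)[0]) for k in range(5)]
        cfg = ClfTrainConfig(seed=0, alpha=0.05, epochs=400, batch_size=5)
        clf, report = train_classifier(crops[idx], labels[idx], cfg)
        pred = clf.predict_proba(crops[idx]).argmax(axis=1)
        assert np.array_equal(pred, labels[idx])

    def test_missing_class_rejected(self, benchmark_corpus):
        crops, labels = benchmark_corpus
        keep = labels != 3
        with pytest.raises(ValueError, match="missing"):
            train_classifier(crops[keep][:50], labels[keep][:50])

    def test_training_deterministic(self, benchmark_corpus):
        crops, labels = benchmark_corpus
        cfg = ClfTrainConfig(seed=7, epochs=8)
        _, r1 = train_classifier(crops[:300], labels[:300], cfg)
        _, r2 = train_classifier(crops[:300], labels[:300], cfg)
        assert r1["validation_accuracy"] == r2["validation_accuracy"]
        assert r1["trace"] == r2["trace"]

    def test_rotation_invariance_of_accuracy(self, trained_classifier,
                                             benchmark_corpus):
        """Accuracy changes by <= 2 points under 90-degree crop rotations."""
        clf, _ = trained_classifier
        crops, labels = benchmark_corpus
        sub, y = crops[:400], labels[:400]
        base = np.mean(clf.predict_proba(sub).argmax(axis=1) == y)
        for k in (1, 2, 3):
            rot = np.rot90(sub, k=k, axes=(1, 2))
            acc = np.mean(clf.predict_proba(rot).argmax(axis=1) == y)
            assert abs(acc - base) <= 0.02

    def test_model_roundtrip(self, trained_classifier, benchmark_corpus,
                             tmp_path):
        clf, _ = trained_classifier
        crops, _ = benchmark_corpus
        path = tmp_path / "clf.npz"
        clf.save(path)
        loaded = TileClassifier.load(path)
        assert np.array_equal(clf.predict_proba(crops[:16]),
                              loaded.predict_proba(crops[:16]))

    def test_classify_tile_contract(self, trained_classifier, benchmark_corpus):
        clf, _ = trained_classifier
        crops, _ = benchmark_corpus
        res = classify_tile(crops[0], clf, tile_id=9)
        assert res.tile_id == 9
        assert res.confidence == pytest.approx(res.probabilities.max())


class TestConfidenceHistograms:
    def _result(self, k, conf):
        p = np.full(5, (1 - conf) / 4)
        p[k] = conf
        return ClassResult(0, IceClass(k), p, conf)

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(3)
        results = [self._result(int(rng.integers(5)),
                                float(rng.uniform(0.3, 1.0)))
                   for _ in range(100)]
        hists = confidence_histograms(results, bins=10)
        edges = np.linspace(0, 1, 11)
        for k in range(5):
            confs = [r.confidence for r in results if r.ice_class.index == k]
            counts, _ = np.histogram(confs, bins=edges)
            assert np.array_equal(hists[k][0], counts)
            assert hists[k][0].sum() == len(confs)

    def test_certain_results_spike_top_bin(self):
        results = [self._result(2, 1.0) for _ in range(7)]
        hists = confidence_histograms(results, bins=20)
        assert hists[2][0][-1] == 7 and hists[2][0][:-1].sum() == 0

    def test_uniform_vectors_land_in_point_two_bin(self):
        results = [ClassResult(0, IceClass(0), np.full(5, 0.2), 0.2)
                   for _ in range(3)]
        hists = confidence_histograms(results, bins=20)
        # 0.2 falls in the [0.2, 0.25) bin
        assert hists[0][0][4] == 3

    def test_empty_input_empty_histograms(self):
        hists = confidence_histograms([])
        assert all(h[0].sum() == 0 for h in hists.values())

    def test_csv_export(self, tmp_path):
        import pandas as pd
        from icegrid.classification import histograms_to_csv
        hists = confidence_histograms([self._result(2, 0.9)] * 4, bins=10)
        path = tmp_path / "hists.csv"
        histograms_to_csv(hists, path)
        df = pd.read_csv(path)
        assert len(df) == 50
        assert df[df["class"] == 2]["count"].sum() == 4
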