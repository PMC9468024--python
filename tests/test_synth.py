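"""Synthetic scene generator: thickness fields, rendering, EM pairs, datasets."""

import numpy as np
import pytest

import icegrid as ig
from icegrid.optics import FilmStack, band_averaged_reflectance
from icegrid.synth import GridSpec, ClassModel, make_scene, hole_array_field
from icegrid.thickness import thickness_map


class TestThicknessFields:
    @pytest.mark.parametrize("label", [1, 2, 3, 4])
    def test_square_mean_falls_in_class_bin(self, label):
        model = ClassModel()
        lo, hi = model.bins[label]
        for seed in range(10):
            f = ig.sample_thickness_field(label, model=model, seed=seed)
            assert lo <= f.mean <= hi

    def test_class2_bin_contains_typical_particle_size(self):
        # class 2 ("optimal") is centred near 40 nm film thickness
        model = ClassModel()
        lo, hi = model.bins[2]
        assert lo <= 40.0 <= hi

    def test_class1_zero_spread_is_constant(self):
        model = ClassModel(mean_sd={1: 0.0, 2: 5.0, 3: 4.0},
                           field_sd={0: 0, 1: 0.0, 2: 3, 3: 4, 4: 4})
        f = ig.sample_thickness_field(1, model=model, seed=3)
        assert np.allclose(f.t_nm, model.centers[1])

    def test_class4_droplet_reaches_half_micron_scale(self):
        for seed in range(5):
            f = ig.sample_thickness_field(4, seed=seed)
            assert f.t_nm.max() >= 400.0

    def test_identical_seed_identical_field(self):
        a = ig.sample_thickness_field(3, seed=11)
        b = ig.sample_thickness_field(3, seed=11)
        assert np.array_equal(a.t_nm, b.t_nm)

    def test_class_means_monotone_over_seeds(self):
        means = [np.mean([ig.sample_thickness_field(k, seed=s).mean
                          for s in range(100)]) for k in (1, 2, 3, 4)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            ig.sample_thickness_field(5, seed=0)


class TestRendering:
    def test_uniform_square_renders_flat_colour(self):
        model = ClassModel(mean_sd={1: 0.0, 2: 5.0, 3: 4.0},
                           field_sd={0: 0, 1: 0.0, 2: 3, 3: 4, 4: 4})
        scene = make_scene(shape=(256, 256), magnification=5, angle_deg=0.0,
                           class_mix=(0, 1, 0, 0, 0), model=model, seed=2)
        intf, truth = ig.render_interferogram(scene, noise_sd=0.0, seed=0)
        rec = next(r for r in truth.squares if not r["border"])
        r0, c0, r1, c1 = rec["bbox"]
        sel = truth.tile_mask[r0:r1, c0:c1].astype(bool)
        sub = intf.pixels[r0:r1, c0:c1]
        for c in range(3):
            vals = sub[..., c][sel]
            # constant thickness => constant reflectance; the foil holes
            # differ from the support only by the uniform offset
            assert np.unique(np.round(vals, 10)).size <= 2

    def test_pixels_match_film_reflectance_oracle(self):
        """Rendered channels equal the two-beam model of the true thickness."""
        grid = GridSpec(support_offset=0.0)
        scene = make_scene(shape=(256, 256), magnification=5, angle_deg=7.0,
                           class_mix=(0, 0, 0, 0, 1), grid=grid, seed=5)
        intf, truth = ig.render_interferogram(scene, noise_sd=0.0, seed=0)
        stack = FilmStack()
        sel = truth.tile_mask.astype(bool)
        expected = band_averaged_reflectance(truth.thickness_nm[sel]) \
            * (grid.film_display_gain / stack.max_reflectance)
        got = intf.pixels[sel]
        assert np.abs(got - np.clip(expected, 0, 1)).max() < 1e-3

    def test_droplet_shows_multiple_fringes(self):
        from scipy.signal import argrelmax
        grid = GridSpec(support_offset=0.0)
        scene = make_scene(shape=(384, 384), magnification=5, angle_deg=0.0,
                           class_mix=(0, 0, 0, 0, 1), grid=grid, seed=9)
        intf, truth = ig.render_interferogram(scene, noise_sd=0.0, seed=0)
        r, c = np.unravel_index(np.argmax(truth.thickness_nm),
                                truth.thickness_nm.shape)
        profile = intf.pixels[r, :, 0]  # 433 nm channel through the droplet
        peaks = argrelmax(profile, order=2)[0]
        assert len(peaks) >= 2  # at least two full interference fringes

    def test_render_deterministic(self):
        scene = make_scene(shape=(256, 256), magnification=10, seed=4)
        a, _ = ig.render_interferogram(scene, noise_sd=0.02, seed=8)
        b, _ = ig.render_interferogram(scene, noise_sd=0.02, seed=8)
        assert np.array_equal(a.pixels, b.pixels)

    def test_too_small_raster_rejected(self):
        with pytest.raises(ValueError):
            make_scene(shape=(64, 64), magnification=10, seed=0)

    def test_masks_match_geometry(self):
        scene = make_scene(shape=(256, 256), magnification=5, angle_deg=0.0,
                           seed=6)
        intf, truth = ig.render_interferogram(scene, noise_sd=0.0, seed=0)
        # bars are bright and uniform; every mask-0 pixel must be a bar pixel
        bar_level = scene.grid.bar_reflectance
        bg = intf.pixels[truth.tile_mask == 0]
        assert np.allclose(bg, bar_level)


class TestEMPairs:
    def test_zero_thickness_no_attenuation(self):
        pair = ig.simulate_em_pair(np.zeros((8, 8)), noise_sd=0.0)
        assert np.array_equal(pair.filtered, pair.unfiltered)

    def test_one_mean_free_path(self):
        lam = 322.0
        pair = ig.simulate_em_pair(np.full((4, 4), lam), lam_inel=lam)
        assert np.allclose(pair.filtered, pair.unfiltered / np.e)

    def test_closed_form_ratio(self):
        pair = ig.simulate_em_pair(np.full((4, 4), 56.0), lam_inel=322.0)
        assert np.allclose(pair.filtered / pair.unfiltered, np.exp(-56.0 / 322.0))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ig.simulate_em_pair(np.ones((4, 4)), lam_inel=0.0)
        with pytest.raises(ValueError):
            ig.simulate_em_pair(np.ones((4, 4)), I0=-5.0)

    def test_hole_array_geometry(self):
        f = ig.sample_thickness_field(2, seed=0)
        t_eff, centers, radius = hole_array_field(f, n_holes=(5, 4))
        assert len(centers) == 20
        # inside a hole the effective thickness is the bare film
        cy, cx = centers[0].astype(int)
        assert t_eff[cy, cx] == pytest.approx(
            np.sort(t_eff.ravel())[0], abs=20.0)


class TestDatasets:
    def test_all_class2_mix_labels_every_tile_2(self):
        items, manifest = ig.make_dataset(1, class_mix=(0, 0, 1, 0, 0),
                                          magnification=5, seed=3)
        labels = [r["label"] for r in manifest[0]["squares"]]
        assert labels and set(labels) == {2}

    def test_uniform_mix_histogram(self):
        _, manifest = ig.make_dataset(10, magnification=5, seed=1)
        labels = [r["label"] for e in manifest for r in e["squares"]]
        counts = np.bincount(labels, minlength=5)
        n = len(labels)
        # within ~4 sigma of binomial sampling around n/5
        sigma = np.sqrt(n * 0.2 * 0.8)
        assert np.all(np.abs(counts - n / 5) < 4 * sigma)

    def test_manifest_deterministic(self):
        _, m1 = ig.make_dataset(2, magnification=10, seed=5)
        _, m2 = ig.make_dataset(2, magnification=10, seed=5)
        assert m1 == m2

    def test_written_layout(self, tmp_path):
        ig.make_dataset(1, magnification=5, seed=0, out_dir=tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "config.yaml").exists()
        assert (tmp_path / "images" / "img_0000.png").exists()
        assert (tmp_path / "masks" / "mask_0000.png").exists()

    def test_roundtrip_inversion_via_thickness_map(self):
        f = ig.sample_thickness_field(3, seed=2)
        tm = thickness_map(ig.simulate_em_pair(f, noise_sd=0.0))
        assert np.abs(tm.t_nm - f.t_nm).max() < 1e-9
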