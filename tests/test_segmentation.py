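"""Spectral-index segmentation, clustering, LVQ, pixel labelling."""

import logging

import numpy as np
import pytest

from cuscuta_hsi import (BandCalibration, SpectralCube, cloth_background,
                         default_scene_spec, kmeans_cluster,
                         label_plant_pixels, lvq_train, ndvi_map,
                         ndvi_segment, ndwi_kmeans_segment, ndwi_map,
                         render_scene, xmeans_cluster)


def cube_from_bands(nir, red, wavelengths=(620.0, 830.0)):
    """2-band cube with the given per-pixel values (band 1 = NIR)."""
    nir, red = np.atleast_2d(nir), np.atleast_2d(red)
    arr = np.stack([red, nir], axis=-1).astype(float)
    return SpectralCube(arr, BandCalibration(np.asarray(wavelengths)))


class TestIndexMaps:
    def test_ndvi_formula(self):
        cube = cube_from_bands(0.8, 0.1)
        assert ndvi_map(cube, 1, 0)[0, 0] == pytest.approx(0.7 / 0.9)

    def test_equal_bands_give_zero(self):
        cube = cube_from_bands(0.4, 0.4)
        assert ndvi_map(cube, 1, 0)[0, 0] == 0.0

    def test_zero_zero_convention(self):
        cube = cube_from_bands(0.0, 0.0)
        assert ndvi_map(cube, 1, 0)[0, 0] == 0.0

    def test_identical_band_indices_rejected(self, tiny_cube):
        with pytest.raises(ValueError, match="must differ"):
            ndvi_map(tiny_cube, 1, 1)

    def test_ndwi_same_conventions(self):
        cube = cube_from_bands(0.6, 0.2, wavelengths=(1098.0, 1655.0))
        assert ndwi_map(cube, 1, 0)[0, 0] == pytest.approx(0.5)
        assert ndwi_map(cube_from_bands(0.3, 0.3), 1, 0)[0, 0] == 0.0

    def test_gain_invariance(self, vnir_scene):
        cube, _ = vnir_scene
        gain = np.random.default_rng(0).uniform(0.5, 2.0,
                                                (cube.lines, cube.samples, 1))
        gained = SpectralCube(cube.reflectance * gain, cube.calibration)
        np.testing.assert_allclose(ndvi_map(gained), ndvi_map(cube), atol=1e-12)


class TestNdviSegment:
    def test_zero_noise_scene_recovered_exactly(self):
        cube, truth = render_scene(default_scene_spec(seed=9, noise_sd=0.0,
                                                      lines=64, samples=64))
        mask = ndvi_segment(cube)
        np.testing.assert_array_equal(mask.mask, truth.label_map > 0)

    def test_extreme_thresholds(self, vnir_scene):
        cube, _ = vnir_scene
        assert ndvi_segment(cube, 1.0).n_plant == 0
        assert ndvi_segment(cube, -1.0).n_plant == cube.lines * cube.samples

    @pytest.mark.parametrize("lo,hi", [(0.3, 0.6), (0.6, 0.75), (0.75, 0.9)])
    def test_monotone_in_threshold(self, vnir_scene, lo, hi):
        cube, _ = vnir_scene
        assert ndvi_segment(cube, hi).n_plant <= ndvi_segment(cube, lo).n_plant


class TestNdwiKmeans:
    def test_swir_scene_recovered(self):
        from cuscuta_hsi import savitzky_golay_smooth

        cube, truth = render_scene(default_scene_spec(
            profile="swir", seed=2, lines=64, samples=64, noise_sd=0.003))
        mask = ndwi_kmeans_segment(savitzky_golay_smooth(cube), seed=0)
        agreement = (mask.mask == (truth.label_map > 0)).mean()
        assert agreement > 0.99

    def test_constant_map_rejected(self, swir_cal):
        cube = SpectralCube(np.full((4, 4, len(swir_cal)), 0.5), swir_cal)
        with pytest.raises(ValueError, match="constant"):
            ndwi_kmeans_segment(cube)

    def test_deterministic_under_seed(self):
        cube, _ = render_scene(default_scene_spec(profile="swir", seed=2,
                                                  lines=48, samples=48))
        m1 = ndwi_kmeans_segment(cube, seed=4)
        m2 = ndwi_kmeans_segment(cube, seed=4)
        np.testing.assert_array_equal(m1.mask, m2.mask)


def gaussian_blobs(rng, centers, n_per=60, sd=0.05):
    points = np.vstack([rng.normal(c, sd, size=(n_per, len(c)))
                        for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return points, labels


class TestKMeans:
    def test_two_blobs_partition_recovered(self):
        rng = np.random.default_rng(0)
        points, labels = gaussian_blobs(rng, [(0, 0), (3, 3)])
        result = kmeans_cluster(points, k=2, seed=1)
        # partition equality up to cluster relabelling
        first = result.labels[labels == 0]
        second = result.labels[labels == 1]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_k_equals_n_gives_zero_wcss(self):
        points = np.random.default_rng(1).random((8, 3))
        result = kmeans_cluster(points, k=8, seed=0)
        assert result.wcss == pytest.approx(0.0, abs=1e-20)

    def test_wcss_trace_non_increasing(self):
        points = np.random.default_rng(2).random((200, 4))
        result = kmeans_cluster(points, k=4, seed=0)
        assert np.all(np.diff(result.wcss_trace) <= 1e-9)

    def test_final_wcss_not_worse_than_seeding(self):
        points = np.random.default_rng(3).random((150, 3))
        result = kmeans_cluster(points, k=3, seed=0)
        assert result.wcss <= result.wcss_trace[0] + 1e-12

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), k=5)


class TestXMeans:
    def test_three_blobs_choose_three(self):
        rng = np.random.default_rng(4)
        points, _ = gaussian_blobs(rng, [(0, 0), (4, 0), (2, 4)], n_per=80)
        _, k = xmeans_cluster(points, k_min=2, k_max=6, seed=0)
        assert k == 3

    def test_fixed_range_reduces_to_kmeans(self):
        rng = np.random.default_rng(5)
        points, _ = gaussian_blobs(rng, [(0, 0), (4, 4)])
        labels_x, k = xmeans_cluster(points, k_min=2, k_max=2, seed=7)
        assert k == 2
        labels_k = kmeans_cluster(points, k=2, seed=7).labels
        np.testing.assert_array_equal(labels_x, labels_k)

    def test_deterministic(self):
        points = np.random.default_rng(6).random((120, 3))
        a = xmeans_cluster(points, 2, 5, seed=3)
        b = xmeans_cluster(points, 2, 5, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            xmeans_cluster(np.zeros((10, 2)), k_min=4, k_max=2)


class TestLVQ:
    def test_separable_classes_fully_learned(self):
        rng = np.random.default_rng(7)
        points, labels = gaussian_blobs(rng, [(0, 0), (5, 5)], sd=0.3)
        model = lvq_train(points, labels, epochs=10, seed=0)
        assert (model.predict(points) == labels).mean() == 1.0

    def test_zero_learning_rate_keeps_initial_prototypes(self):
        rng = np.random.default_rng(8)
        points, labels = gaussian_blobs(rng, [(0, 0), (5, 5)], n_per=20)
        model = lvq_train(points, labels, learning_rate=0.0, seed=3)
        # each prototype must still be an actual training sample of its class
        for proto, cls in zip(model.prototypes, model.prototype_labels):
            members = points[labels == cls]
            assert np.any(np.all(np.isclose(members, proto), axis=1))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        points, labels = gaussian_blobs(rng, [(0, 0), (3, 3)], sd=0.5)
        m1 = lvq_train(points, labels, seed=5)
        m2 = lvq_train(points, labels, seed=5)
        np.testing.assert_array_equal(m1.prototypes, m2.prototypes)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="example"):
            lvq_train(np.zeros((0, 2)), np.array([]))


class TestLabelPlantPixels:
    def test_count_and_label(self, vnir_scene):
        cube, truth = vnir_scene
        mask = ndvi_segment(cube)
        table = label_plant_pixels(mask, cube, "campestris", "img0")
        assert len(table) == mask.n_plant
        assert set(table.labels) == {"campestris"}
        assert set(table.meta["image_id"]) == {"img0"}

    def test_empty_mask_warns(self, vnir_scene, caplog):
        cube, _ = vnir_scene
        mask = ndvi_segment(cube, threshold=1.0)
        with caplog.at_level(logging.WARNING, logger="cuscuta_hsi.segmentation"):
            table = label_plant_pixels(mask, cube, "host", "img1")
        assert len(table) == 0
        assert "empty mask" in caplog.text

    def test_per_class_counts_match_masks(self):
        from cuscuta_hsi import concat_tables, default_species_models

        tables = []
        expected = {}
        for ci, model in enumerate(default_species_models()):
            cube, truth = render_scene(default_scene_spec(
                seed=50 + ci, classes=[model], lines=48, samples=48,
                noise_sd=0.0))
            mask = ndvi_segment(cube)
            expected[model.name] = mask.n_plant
            tables.append(label_plant_pixels(mask, cube, model.name, f"i{ci}"))
        combined = concat_tables(tables)
        counts = combined.meta.groupby("label").size().to_dict()
        assert counts == expected
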