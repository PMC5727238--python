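import numpy as np
import pytest

from dectmap import (
    AttenuationVolume,
    NoiseSpec,
    correlation_histogram2d,
    decompose_volume,
    make_organ_phantom,
    mean_attenuation,
    relative_volume_series,
    sample_volume,
    simulate_staining_series,
    uptake_summary,
)


class TestSampleVolume:
    def test_solid_block_count_times_voxel_cubed(self):
        data = np.zeros((20, 20, 20))
        data[5:15, 5:15, 5:15] = 1.0
        vol = AttenuationVolume(data, 2.0)
        assert sample_volume(vol, 0.5) == pytest.approx(1000 * 8.0)

    def test_all_below_threshold_is_zero(self):
        vol = AttenuationVolume(np.zeros((10, 10, 10)), 2.0)
        assert sample_volume(vol, 0.5) == 0.0

    def test_enclosed_cavity_counted(self):
        """A hollow shell's internal chamber contributes to the volume."""
        data = np.zeros((20, 20, 20))
        data[4:16, 4:16, 4:16] = 1.0
        data[7:13, 7:13, 7:13] = 0.0  # air-filled chamber
        vol = AttenuationVolume(data, 1.0)
        assert sample_volume(vol, 0.5) == pytest.approx(12**3)

    def test_border_reaching_notch_not_counted(self):
        data = np.zeros((20, 20, 20))
        data[4:16, 4:16, 4:16] = 1.0
        data[4:16, 9:11, 9:11] = 0.0  # channel open to the border
        vol = AttenuationVolume(data, 1.0)
        assert sample_volume(vol, 0.5) == pytest.approx(12**3 - 12 * 4)

    def test_container_removed_before_thresholding(self):
        data = np.zeros((10, 10, 10))
        data[2:8, 2:8, 2:8] = 1.0
        container = np.zeros_like(data, dtype=bool)
        container[2:8, 2:8, 2:4] = True
        vol = AttenuationVolume(data, 1.0)
        assert sample_volume(vol, 0.5, container) == pytest.approx(6 * 6 * 4)

    def test_invariant_under_lattice_rotations(self):
        rng = np.random.default_rng(0)
        data = (rng.random((12, 12, 12)) > 0.6).astype(float)
        vol = AttenuationVolume(data, 1.0)
        base = sample_volume(vol, 0.5)
        for axes in ((0, 1), (0, 2), (1, 2)):
            rotated = AttenuationVolume(np.rot90(data, axes=axes), 1.0)
            assert sample_volume(rotated, 0.5) == base

    def test_bad_voxel_size_rejected(self):
        vol = AttenuationVolume(np.ones((4, 4, 4)), 1.0)
        with pytest.raises(ValueError):
            sample_volume(vol, 0.5, voxel_size_um=0.0)


class TestRelativeVolumeSeries:
    def test_simple_ratio(self):
        ts = relative_volume_series([(0.0, 100.0), (30.0, 80.0)])
        assert np.allclose(ts.relative, [1.0, 0.8])

    def test_constant_volumes_all_unity(self):
        ts = relative_volume_series([(0.0, 5.0), (30.0, 5.0), (60.0, 5.0)])
        assert np.allclose(ts.relative, 1.0)

    def test_scale_free(self):
        a = relative_volume_series([(0.0, 10.0), (30.0, 7.0)])
        b = relative_volume_series([(0.0, 1000.0), (30.0, 700.0)])
        assert np.allclose(a.relative, b.relative)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_volume_series([(0.0, 0.0), (30.0, 1.0)])

    def test_programmed_shrinkage_recovered_end_to_end(self, small_organ_spec, calset):
        """An 80% first-round volume ratio is measured as ~0.80 thereafter."""
        series = simulate_staining_series(
            small_organ_spec,
            calset,
            [0.0, 30.0, 60.0],
            [1.0, 0.8, 1.0],
            NoiseSpec(sigma=0.02, seed=17),
        )
        thr = 0.5 * calset.le["pmma"]
        rows = [
            (t, sample_volume(le, thr, truth.container_mask))
            for t, le, _, truth in series
        ]
        ts = relative_volume_series(rows)
        assert ts.relative[0] == 1.0
        assert ts.relative[1] == pytest.approx(0.80, abs=0.02)
        assert ts.relative[2] == pytest.approx(0.80, abs=0.02)


class TestMeanAttenuation:
    def test_constant_region(self):
        vol = AttenuationVolume(np.full((6, 6, 6), 0.42), 1.0)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:4] = True
        assert mean_attenuation(vol, mask) == pytest.approx(0.42)

    def test_two_level_region_averages(self):
        data = np.zeros((4, 4, 4))
        data[:2] = 0.2
        data[2:] = 0.6
        vol = AttenuationVolume(data, 1.0)
        assert mean_attenuation(vol, np.ones_like(data, bool)) == pytest.approx(0.4)

    def test_empty_mask_rejected(self):
        vol = AttenuationVolume(np.ones((4, 4, 4)), 1.0)
        with pytest.raises(ValueError):
            mean_attenuation(vol, np.zeros((4, 4, 4), bool))

    def test_staining_series_means_increase(self, small_organ_spec, calset):
        series = simulate_staining_series(
            small_organ_spec, calset, [0.0, 30.0, 60.0], None, NoiseSpec()
        )
        means = [mean_attenuation(le, truth.organ_mask) for _, le, _, truth in series]
        assert means[0] < means[1] < means[2]


class TestCorrelationHistogram:
    def test_constant_volumes_single_bin(self):
        vol_le = AttenuationVolume(np.full((5, 5, 5), 0.3), 1.0)
        vol_he = AttenuationVolume(np.full((5, 5, 5), 0.2), 1.0)
        edges = np.linspace(0.0, 1.0, 11)
        hist = correlation_histogram2d(vol_le, vol_he, le_edges=edges, he_edges=edges)
        assert hist.counts.sum() == 125
        assert (hist.counts > 0).sum() == 1

    def test_conservation_with_out_of_range_values(self, rng):
        vol_le = AttenuationVolume(rng.normal(0.5, 1.0, (8, 8, 8)), 1.0)
        vol_he = AttenuationVolume(rng.normal(0.3, 1.0, (8, 8, 8)), 1.0)
        mask = rng.random((8, 8, 8)) > 0.4
        edges = np.linspace(0.2, 0.6, 5)  # deliberately narrow
        hist = correlation_histogram2d(vol_le, vol_he, mask, edges, edges)
        assert hist.counts.sum() == mask.sum()

    def test_two_material_phantom_forms_two_clusters(self, calset):
        from dectmap import CalibrationPhantomGeometry, make_calibration_phantom

        sigma = 0.01
        geom = CalibrationPhantomGeometry()
        vol_le, vol_he, labels = make_calibration_phantom(
            geom, calset, NoiseSpec(sigma=sigma, seed=5)
        )
        mask = labels != 2  # air + PMMA only
        hist = correlation_histogram2d(vol_le, vol_he, mask, bins=64)
        # cluster centroids recovered from the histogram itself
        le_c = 0.5 * (hist.le_edges[:-1] + hist.le_edges[1:])
        he_c = 0.5 * (hist.he_edges[:-1] + hist.he_edges[1:])
        w = hist.counts
        split = 0.5 * (calset.le["air"] + calset.le["pmma"])
        lo = le_c < split
        for sel, name in ((lo, "air"), (~lo, "pmma")):
            wsel = w[sel, :]
            cle = (wsel.sum(axis=1) @ le_c[sel]) / wsel.sum()
            che = (wsel.sum(axis=0) @ he_c) / wsel.sum()
            assert abs(cle - calset.le[name]) < 3 * sigma
            assert abs(che - calset.he[name]) < 3 * sigma

    def test_non_monotone_edges_rejected(self):
        vol = AttenuationVolume(np.zeros((4, 4, 4)), 1.0)
        with pytest.raises(ValueError):
            correlation_histogram2d(vol, vol, le_edges=np.array([0.0, 1.0, 0.5]))


class TestUptakeSummary:
    def test_constant_fraction_region(self, unit_cap_spec, calset):
        vol_le, vol_he, truth = make_organ_phantom(unit_cap_spec, calset, 1e10)
        fmap = decompose_volume(vol_le, vol_he, calset, mask=truth.organ_mask)
        s = uptake_summary(fmap, {"organ": truth.organ_mask}, 1e10)
        assert s.per_label["organ"]["mean"] == pytest.approx(1.0, abs=1e-3)
        assert s.per_label["organ"]["max"] == pytest.approx(1.0, abs=1e-3)

    def test_faster_compartment_dominates_at_all_times(self, small_organ_spec, calset):
        for t in (15.0, 60.0, 150.0):
            vol_le, vol_he, truth = make_organ_phantom(small_organ_spec, calset, t)
            fmap = decompose_volume(vol_le, vol_he, calset, mask=truth.organ_mask)
            s = uptake_summary(fmap, truth.compartment_masks, t)
            assert s.per_label["heart"]["mean"] > s.per_label["lung"]["mean"]

    def test_counts_partition_organ(self, small_organ_spec, calset):
        vol_le, vol_he, truth = make_organ_phantom(small_organ_spec, calset, 30.0)
        fmap = decompose_volume(vol_le, vol_he, calset, mask=truth.organ_mask)
        s = uptake_summary(fmap, truth.compartment_masks, 30.0)
        counts = sum(v["count"] for v in s.per_label.values())
        assert counts == truth.organ_mask.sum()

    def test_absent_label_reported_with_zero_count(self, small_organ_spec, calset):
        vol_le, vol_he, truth = make_organ_phantom(small_organ_spec, calset, 30.0)
        fmap = decompose_volume(vol_le, vol_he, calset, mask=truth.organ_mask)
        empty = np.zeros(truth.organ_mask.shape, dtype=bool)
        s = uptake_summary(fmap, {"esophagus": empty}, 30.0)
        assert s.per_label["esophagus"]["count"] == 0

    def test_overlapping_masks_rejected(self, small_organ_spec, calset):
        vol_le, vol_he, truth = make_organ_phantom(small_organ_spec, calset, 30.0)
        fmap = decompose_volume(vol_le, vol_he, calset, mask=truth.organ_mask)
        with pytest.raises(ValueError, match="overlap"):
            uptake_summary(
                fmap, {"a": truth.organ_mask, "b": truth.organ_mask}, 30.0
            )

    def test_programmed_overconcentration_recovered(self, small_organ_spec, calset):
        """A heart programmed to concentrate stain to 1.3x calibration is
        reported with max F_stain ~ 1.3 by the soft decomposition."""
        vol_le, vol_he, truth = make_organ_phantom(small_organ_spec, calset, 150.0)
        fmap = decompose_volume(vol_le, vol_he, calset, "three_material_soft",
                                mask=truth.organ_mask)
        s = uptake_summary(fmap, truth.compartment_masks, 150.0)
        assert s.per_label["heart"]["max"] == pytest.approx(1.3, abs=0.05)
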