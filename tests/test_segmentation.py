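"""Segmentation, cropping, spheroid/cell splitting and the reference surface."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from spheroquant import (
    VoxelVolume,
    crop_at_widest,
    generate_volume,
    mean_intensity,
    segment_foreground,
    smoothed_reference_surface,
    split_spheroid_and_cells,
)
from spheroquant.volumes import LabeledMask

from conftest import rasterize_sphere, sphere_mask


class TestSegmentForeground:
    def test_uniform_zero_volume_yields_empty_mask_with_warning(self):
        volume = VoxelVolume(np.zeros((5, 5, 5)), (1, 1, 1))
        with pytest.warns(UserWarning, match="no foreground"):
            mask = segment_foreground(volume)
        assert mask.n_labels == 0

    def test_noise_free_two_spheres_recover_rasterized_truth_exactly(
        self, two_sphere_scenario, two_sphere_volume
    ):
        volume, _ = two_sphere_volume
        mask = segment_foreground(volume, method="fixed", threshold=100.0)
        assert mask.n_labels == 2
        truth_spheroid = rasterize_sphere(
            two_sphere_scenario.spheroid_radius, two_sphere_scenario.spheroid_center,
            two_sphere_scenario.grid_shape, two_sphere_scenario.voxel_spacing,
        )
        cell = two_sphere_scenario.cells[0]
        truth_cell = rasterize_sphere(
            cell.semi_axes[0], cell.center,
            two_sphere_scenario.grid_shape, two_sphere_scenario.voxel_spacing,
        )
        counts = sorted(mask.voxel_count(lid) for lid in mask.label_ids)
        assert counts == sorted(
            [int(truth_spheroid.sum()), int(truth_cell.sum())]
        )
        assert np.array_equal(mask.labels > 0, truth_spheroid | truth_cell)

    def test_otsu_recovers_foreground_under_mild_noise(self, two_sphere_scenario):
        import dataclasses

        noisy = dataclasses.replace(two_sphere_scenario, noise_sigma=8.0)
        volume, _ = generate_volume(noisy)
        truth = rasterize_sphere(
            noisy.spheroid_radius, noisy.spheroid_center,
            noisy.grid_shape, noisy.voxel_spacing,
        ) | rasterize_sphere(
            noisy.cells[0].semi_axes[0], noisy.cells[0].center,
            noisy.grid_shape, noisy.voxel_spacing,
        )
        mask = segment_foreground(volume, method="otsu")
        recovered = np.count_nonzero((mask.labels > 0) & truth) / truth.sum()
        assert recovered >= 0.99

    def test_min_volume_removes_specks(self):
        data = np.zeros((10, 10, 10))
        data[5, 5, 5] = 200.0  # 1 μm³ speck
        data[1:4, 1:7, 1:7] = 200.0  # 108 μm³ object
        mask = segment_foreground(VoxelVolume(data, (1, 1, 1)), "fixed", threshold=100)
        assert mask.n_labels == 1

    def test_fixed_method_requires_threshold(self):
        volume = VoxelVolume(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError, match="threshold"):
            segment_foreground(volume, method="fixed")


class TestCropAtWidest:
    def test_sphere_widest_at_equator(self):
        # radius 30 μm sphere, z spacing 3 μm, top tangent to the face
        spacing = (3.0, 2.0, 2.0)
        shape = (22, 40, 40)
        binary = rasterize_sphere(30.0, (30.0, 40.0, 40.0), shape, spacing)
        mask = LabeledMask(binary.astype(np.int32), spacing)
        cropped, z_depth = crop_at_widest(mask)
        assert z_depth == pytest.approx(30.0, abs=spacing[0])
        assert cropped.shape[0] == int(round(z_depth / spacing[0])) + 1

    def test_hemisphere_crop_depth_equals_radius(self):
        spacing = (3.0, 2.0, 2.0)
        full = rasterize_sphere(30.0, (30.0, 40.0, 40.0), (22, 40, 40), spacing)
        hemi = full[:11]  # already cut at the equator
        mask = LabeledMask(hemi.astype(np.int32), spacing)
        _, z_depth = crop_at_widest(mask)
        assert abs(z_depth - 30.0) <= spacing[0]

    def test_tie_breaks_toward_imaging_face(self):
        labels = np.zeros((4, 6, 6), dtype=np.int32)
        labels[1, 1:5, 1:5] = 1
        labels[2, 1:5, 1:5] = 1  # same cross-section area as slice 1
        cropped, z_depth = crop_at_widest(LabeledMask(labels, (2.0, 1.0, 1.0)))
        assert cropped.shape[0] == 2  # crop ends at slice 1, not 2
        assert z_depth == 0.0  # widest plane is the spheroid's topmost slice

    def test_acquisition_margin_does_not_inflate_depth(self):
        # same sphere, 5 empty slices above: imaged depth is unchanged
        spacing = (3.0, 2.0, 2.0)
        binary = rasterize_sphere(30.0, (30.0, 40.0, 40.0), (22, 40, 40), spacing)
        padded = np.concatenate([np.zeros((5, 40, 40), dtype=bool), binary])
        _, z_plain = crop_at_widest(LabeledMask(binary.astype(np.int32), spacing))
        _, z_padded = crop_at_widest(LabeledMask(padded.astype(np.int32), spacing))
        assert z_plain == z_padded == pytest.approx(30.0, abs=spacing[0])

    def test_single_slice_mask_is_identity(self):
        labels = np.ones((1, 4, 4), dtype=np.int32)
        cropped, z_depth = crop_at_widest(LabeledMask(labels, (1, 1, 1)))
        assert z_depth == 0.0
        assert cropped.shape == (1, 4, 4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            crop_at_widest(LabeledMask(np.zeros((3, 3, 3), dtype=np.int32), (1, 1, 1)))

    def test_label_counts_conserved_for_objects_inside_crop(
        self, two_sphere_volume
    ):
        volume, _ = two_sphere_volume
        mask = segment_foreground(volume, method="fixed", threshold=100.0)
        cropped, z_depth = crop_at_widest(mask)
        n_kept = cropped.shape[0]
        for lid in mask.label_ids:
            in_crop = np.count_nonzero(mask.labels[:n_kept] == lid)
            if in_crop == mask.voxel_count(lid):  # wholly inside the crop
                assert cropped.voxel_count(lid) == mask.voxel_count(lid)
            else:  # cut objects keep exactly their in-crop voxels
                assert cropped.voxel_count(lid) == in_crop


class TestSplitSpheroidAndCells:
    def test_single_component_means_no_cells(self):
        mask = sphere_mask(8.0)
        spheroid, cells = split_spheroid_and_cells(mask)
        assert spheroid.n_labels == 1
        assert cells.n_labels == 0

    def test_five_cells_around_spheroid(self):
        from spheroquant import CellSpec, ImagingScenario

        cells = [
            CellSpec("sphere", (5.0, 5.0, 5.0), center)
            for center in [(40, 20, 20), (40, 20, 140), (40, 140, 20),
                           (40, 140, 140), (20, 80, 130)]
        ]
        scenario = ImagingScenario(
            grid_shape=(30, 80, 80),
            spheroid_center=(40.0, 80.0, 80.0),
            spheroid_radius=20.0,
            voxel_spacing=(3.0, 2.0, 2.0),
            cells=cells,
            noise_sigma=0.0,
        )
        volume, _ = generate_volume(scenario)
        mask = segment_foreground(volume, method="fixed", threshold=100.0)
        spheroid, cell_mask = split_spheroid_and_cells(mask)
        assert spheroid.n_labels == 1
        assert cell_mask.n_labels == 5

    def test_equal_volume_tie_warns_and_picks_lowest_label(self):
        labels = np.zeros((3, 10, 10), dtype=np.int32)
        labels[1, 1:4, 1:4] = 1
        labels[1, 6:9, 6:9] = 2  # same size
        with pytest.warns(UserWarning, match="tie"):
            spheroid, cells = split_spheroid_and_cells(LabeledMask(labels, (1, 1, 1)))
        assert np.array_equal(spheroid.labels > 0, labels == 1)
        assert cells.n_labels == 1


class TestReferenceSurface:
    def test_closing_a_sphere_is_idempotent_within_a_voxel(self):
        mask = sphere_mask(12.0, spacing=(1.0, 1.0, 1.0))
        reference = smoothed_reference_surface(mask, 6.0)
        raw = mask.labels > 0
        added = reference.mask & ~raw
        if added.any():
            # any added voxel sits within one voxel diagonal of the raw surface
            edt = ndimage.distance_transform_edt(~raw, sampling=mask.spacing)
            assert edt[added].max() <= np.linalg.norm(mask.spacing)

    def test_thin_spike_absorbed_by_smoothing(self):
        mask = sphere_mask(12.0, spacing=(1.0, 1.0, 1.0), pad=24)
        center = tuple(s // 2 for s in mask.shape)
        labels = mask.labels.copy()
        # 20 μm long, 1-voxel-thick spike sticking out along +x
        x0 = center[2] + 12
        labels[center[0], center[1], x0:x0 + 20] = 1
        spiked = LabeledMask(labels, mask.spacing)
        reference = smoothed_reference_surface(spiked, 10.0)
        spike_tip = reference.mask[center[0], center[1], x0 + 15:x0 + 20]
        assert not spike_tip.any()

    def test_reference_encloses_bulk_mass(self):
        # for a protrusion-free spheroid the smoothing must not eat into the
        # bulk: any raw voxel outside the reference lies within one voxel
        # diagonal of it (rasterization slack only)
        mask = sphere_mask(10.0, spacing=(2.0, 1.0, 1.0))
        reference = smoothed_reference_surface(mask, 8.0)
        missing = (mask.labels > 0) & ~reference.mask
        if missing.any():
            edt = ndimage.distance_transform_edt(~reference.mask, sampling=mask.spacing)
            assert edt[missing].max() <= np.linalg.norm(mask.spacing)

    def test_zero_scale_returns_raw_surface(self):
        mask = sphere_mask(8.0)
        reference = smoothed_reference_surface(mask, 0.0)
        assert np.array_equal(reference.mask, mask.labels > 0)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            smoothed_reference_surface(sphere_mask(8.0), -1.0)


class TestMeanIntensity:
    def test_uniform_and_split_intensities(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0] = 1
        mask = LabeledMask(labels, (1, 1, 1))
        data = np.zeros((2, 2, 2))
        data[0, 0] = 10.0
        data[0, 1] = 20.0
        channel = VoxelVolume(data, (1, 1, 1))
        assert mean_intensity(1, mask, channel) == pytest.approx(15.0)

        uniform = VoxelVolume(np.full((2, 2, 2), 7.5), (1, 1, 1))
        assert mean_intensity(1, mask, uniform) == pytest.approx(7.5)

    def test_graded_intensity_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        labels = (rng.random((6, 6, 6)) > 0.5).astype(np.int32)
        labels[0, 0, 0] = 1  # ensure non-empty
        mask = LabeledMask(labels, (1, 1, 1))
        data = rng.random((6, 6, 6)) * 100
        channel = VoxelVolume(data, (1, 1, 1))
        brute = data[labels == 1].sum() / np.count_nonzero(labels)
        assert mean_intensity(1, mask, channel) == pytest.approx(brute, rel=1e-12)

    def test_missing_label_rejected(self):
        mask = sphere_mask(4.0)
        channel = VoxelVolume(np.zeros(mask.shape), mask.spacing)
        with pytest.raises(KeyError):
            mean_intensity(99, mask, channel)
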