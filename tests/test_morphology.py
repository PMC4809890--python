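import numpy as np
import pytest
from skimage.morphology import reconstruction as skimage_reconstruction

from mantis.morphology import (
    Connectivity,
    default_gradient_sigmas,
    filter_small_components,
    multiscale_gradient,
    reconstruct_by_dilation,
    watershed_from_markers,
)
from oracles import reconstruct_oracle, watershed_oracle


class TestReconstructByDilation:
    def test_marker_equals_mask_is_identity(self, rng):
        mask = rng.random((5, 5, 5))
        out = reconstruct_by_dilation(mask, mask)
        np.testing.assert_array_equal(out, mask)

    def test_isolated_peak_suppressed_1d(self):
        # the isolated high value 3 collapses to the surrounding level 1
        mask = np.array([0.0, 5.0, 1.0, 3.0, 1.0])
        marker = np.array([0.0, 5.0, 0.0, 0.0, 0.0])
        out = reconstruct_by_dilation(marker, mask)
        np.testing.assert_array_equal(out, [0.0, 5.0, 1.0, 1.0, 1.0])

    def test_zero_marker_gives_zero(self, rng):
        mask = rng.random((4, 4, 4))
        out = reconstruct_by_dilation(np.zeros_like(mask), mask)
        np.testing.assert_array_equal(out, np.zeros_like(mask))

    def test_marker_above_mask_clipped_with_warning(self):
        mask = np.zeros((3, 3, 3))
        marker = np.full((3, 3, 3), 1e-7)
        with pytest.warns(UserWarning, match="clipping"):
            out = reconstruct_by_dilation(marker, mask)
        np.testing.assert_array_equal(out, mask)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            reconstruct_by_dilation(np.zeros((3, 3)), np.zeros((4, 4)))

    @pytest.mark.parametrize("conn", [Connectivity.FACE, Connectivity.FULL])
    def test_matches_naive_oracle_on_random_volumes(self, conn, rng):
        for _ in range(30):
            shape = tuple(rng.integers(3, 9, size=3))
            mask = rng.random(shape)
            marker = mask * rng.random(shape)
            out = reconstruct_by_dilation(marker, mask, conn)
            np.testing.assert_array_equal(out, reconstruct_oracle(
                marker, mask, conn))

    def test_matches_skimage_reference(self, rng):
        mask = rng.random((10, 10, 10))
        marker = mask * rng.random((10, 10, 10))
        out = reconstruct_by_dilation(marker, mask, Connectivity.FACE)
        ref = skimage_reconstruction(marker, mask, method="dilation",
                                     footprint=Connectivity.FACE.structure(3))
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_idempotent_and_anti_extensive(self, rng):
        mask = rng.random((6, 6, 6))
        marker = mask * rng.random((6, 6, 6))
        r = reconstruct_by_dilation(marker, mask)
        assert (r <= mask + 1e-12).all()
        assert (r >= marker - 1e-12).all()
        np.testing.assert_array_equal(reconstruct_by_dilation(r, mask), r)


class TestWatershedFromMarkers:
    def test_single_marker_floods_everything(self, rng):
        control = rng.random((5, 6, 4))
        markers = np.zeros((5, 6, 4), int)
        markers[2, 3, 1] = 7
        out = watershed_from_markers(control, markers)
        assert (out == 7).all()

    def test_1d_ridge_tie_goes_to_first_inserted(self):
        control = np.array([0.0, 1.0, 9.0, 1.0, 0.0])
        markers = np.array([1, 0, 0, 0, 2])
        out = watershed_from_markers(control, markers)
        # ridge voxel 2 is queued first by the label-1 flood
        np.testing.assert_array_equal(out, [1, 1, 1, 2, 2])

    def test_2d_vertical_ridge_splits_domain(self):
        control = np.zeros((5, 5))
        control[:, 2] = 9.0
        markers = np.zeros((5, 5), int)
        markers[2, 0] = 1
        markers[2, 4] = 2
        out = watershed_from_markers(control, markers)
        assert (out[:, :2] == 1).all()
        assert (out[:, 3:] == 2).all()
        np.testing.assert_array_equal(
            out, watershed_oracle(control, markers, Connectivity.FACE))

    def test_empty_markers_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            watershed_from_markers(np.zeros((3, 3, 3)),
                                   np.zeros((3, 3, 3), int))

    def test_every_voxel_labelled_and_seeds_kept(self, rng):
        control = rng.random((8, 8, 8))
        markers = np.zeros((8, 8, 8), int)
        markers[1, 1, 1] = 1
        markers[6, 6, 6] = 2
        markers[1, 6, 3] = 3
        out = watershed_from_markers(control, markers)
        assert (out > 0).all()
        for lab in (1, 2, 3):
            assert (out[markers == lab] == lab).all()

    @pytest.mark.parametrize("conn", [Connectivity.FACE, Connectivity.FULL])
    def test_matches_bruteforce_priority_flood(self, conn, rng):
        for _ in range(30):
            shape = tuple(rng.integers(3, 9, size=3))
            control = rng.random(shape)
            markers = np.zeros(shape, int)
            nseeds = int(rng.integers(1, 4))
            for lab in range(1, nseeds + 1):
                pos = tuple(rng.integers(0, s) for s in shape)
                markers[pos] = lab
            out = watershed_from_markers(control, markers, conn)
            np.testing.assert_array_equal(
                out, watershed_oracle(control, markers, conn))

    def test_invariant_under_monotone_transform(self, rng):
        control = rng.random((7, 7, 7))
        markers = np.zeros((7, 7, 7), int)
        markers[0, 0, 0] = 1
        markers[6, 6, 6] = 2
        a = watershed_from_markers(control, markers)
        b = watershed_from_markers(control ** 3, markers)
        np.testing.assert_array_equal(a, b)


class TestFilterSmallComponents:
    def test_empty_mask_stays_empty(self):
        out = filter_small_components(np.zeros((4, 4, 4), bool), 10.0)
        assert not out.any()

    def test_physical_volume_threshold_isotropic(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[:4, :10, :10] = True            # 400 voxels = 400 mm^3
        mask[10:16, 10:20, 10:20] = True     # 600 voxels = 600 mm^3
        out = filter_small_components(mask, 500.0, (1, 1, 1))
        assert not out[:4, :10, :10].any()
        assert out[10:16, 10:20, 10:20].all()

    def test_anisotropic_voxels_rescale_volumes(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[:4, :10, :10] = True            # 400 voxels -> 800 mm^3
        mask[10:16, 10:20, 10:20] = True     # 600 voxels -> 1200 mm^3
        out = filter_small_components(mask, 500.0, (1, 1, 2))
        assert out[:4, :10, :10].all()
        assert out[10:16, 10:20, 10:20].all()

    def test_never_adds_voxels(self, rng):
        mask = rng.random((10, 10, 10)) > 0.7
        out = filter_small_components(mask, 5.0, (1, 1, 1))
        assert not (out & ~mask).any()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            filter_small_components(np.ones((3, 3, 3), bool), 0.0)


class TestMultiscaleGradient:
    def test_constant_image_gives_zero(self):
        out = multiscale_gradient(np.full((6, 6, 6), 3.7), [0.25, 1.0])
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_step_edge_peak_matches_closed_form(self):
        # gradient of a smoothed step of height h peaks at h/(sigma*sqrt(2*pi))
        h, sigma = 10.0, 2.0
        img = np.zeros((1, 1, 80))
        img[..., 40:] = h
        out = multiscale_gradient(img, [sigma], (1.0, 1.0, 1.0))
        peak = out.max()
        expected = h / (sigma * np.sqrt(2 * np.pi))
        assert peak == pytest.approx(expected, rel=0.05)
        assert np.argmax(out[0, 0]) in (39, 40)

    def test_default_scales_pair_fine_and_voxel(self):
        assert default_gradient_sigmas((1.0, 1.0, 1.0)) == (0.25, 1.0)
        assert default_gradient_sigmas((0.35, 0.35, 2.0)) == (0.25, 0.35)

    def test_gradient_in_physical_units(self):
        # same ramp, doubled spacing along the ramp axis -> half the gradient
        # per mm (scale large enough for accurate discrete kernels)
        img = np.tile(np.arange(32.0), (4, 4, 1))
        g1 = multiscale_gradient(img, [4.0], (1.0, 1.0, 1.0))
        g2 = multiscale_gradient(img, [4.0], (1.0, 1.0, 2.0))
        mid = (slice(1, 3), slice(1, 3), slice(12, 20))
        np.testing.assert_allclose(g2[mid], 0.5 * g1[mid], rtol=5e-3)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            multiscale_gradient(np.zeros((3, 3, 3)), [0.0])
        with pytest.raises(ValueError, match="scale"):
            multiscale_gradient(np.zeros((3, 3, 3)), [])

    def test_nonnegative_output(self, rng):
        out = multiscale_gradient(rng.random((6, 6, 6)), [0.25, 1.0])
        assert (out >= 0).all()
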