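import numpy as np
import pytest

from nbquant import (SeedPoint, SegmentationParams, detect_maxima_3d,
                     gaussian_blur_3d, segment_bodies)
from oracles import brute_force_maxima

ISO = (0.25, 0.25, 0.25)
CONF = (0.5, 0.2, 0.2)  # anisotropic confocal-like sampling


class TestGaussianBlur:
    def test_constant_image_is_fixed_point(self):
        arr = np.full((10, 12, 14), 100, np.uint8)
        out = gaussian_blur_3d(arr, 1.0, voxel_size=CONF)
        np.testing.assert_allclose(out, 100.0, rtol=1e-10)

    def test_impulse_response_matches_closed_form(self):
        # isotropic 0.25 um voxels, sigma 1 um => 4 voxels per axis
        arr = np.zeros((49, 49, 49))
        arr[24, 24, 24] = 255.0
        out = gaussian_blur_3d(arr, 1.0, voxel_size=ISO)
        expected_centre = 255.0 / (np.sqrt(2 * np.pi) * 4.0) ** 3
        assert abs(out[24, 24, 24] - expected_centre) / expected_centre < 0.01
        # and the profile is the sampled Gaussian
        r = np.arange(-10, 11)
        profile = out[24, 24, 24 + 10] / out[24, 24, 24]
        assert abs(profile - np.exp(-10.0 ** 2 / (2 * 16.0))) < 0.005

    def test_total_intensity_conserved_for_interior_spot(self):
        arr = np.zeros((40, 40, 40))
        arr[20, 20, 20] = 200.0
        out = gaussian_blur_3d(arr, 1.0, voxel_size=ISO)
        assert abs(out.sum() - arr.sum()) / arr.sum() < 0.005

    def test_mean_conserved_on_noisy_interior_dominated_image(self, rng):
        arr = rng.integers(0, 200, (24, 40, 40)).astype(float)
        out = gaussian_blur_3d(arr, 0.6, voxel_size=CONF)
        assert abs(out.mean() - arr.mean()) / arr.mean() < 1e-3

    def test_anisotropy_aware_kernel(self):
        # a physical sigma spans more voxels laterally than axially
        arr = np.zeros((41, 41, 41))
        arr[20, 20, 20] = 1000.0
        out = gaussian_blur_3d(arr, 1.0, voxel_size=CONF)
        axial = out[:, 20, 20]
        lateral = out[20, 20, :]
        # equal physical distance 1 um: 2 voxels axially, 5 laterally
        assert abs(axial[22] - lateral[25]) / lateral[25] < 0.02


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestDetectMaxima:
    def test_single_spot_gives_one_seed_at_centre(self, seg_params):
        arr = np.zeros((16, 32, 32))
        arr[8, 16, 16] = 200.0
        blurred = gaussian_blur_3d(arr, 1.0, voxel_size=CONF)
        blurred *= 200.0 / blurred.max()  # keep peak above the threshold
        seeds = detect_maxima_3d(blurred, seg_params, full_mask(arr.shape), CONF)
        assert len(seeds) == 1
        assert np.linalg.norm(np.subtract(seeds[0].position, (8, 16, 16))) <= 1

    def test_two_equal_spots_below_min_distance_keep_lex_smaller(self, seg_params):
        grid = np.zeros((3, 9, 9))
        grid[1, 4, 3] = 100.0
        grid[1, 4, 4] = 90.0
        grid[1, 4, 5] = 100.0  # equal peak 0.4 um away (< 0.5 um, same z)
        seeds = detect_maxima_3d(grid, seg_params, full_mask(grid.shape), CONF)
        assert [s.position for s in seeds] == [(1, 4, 3)]

    def test_two_spots_two_micrometres_apart_give_two_seeds(self, seg_params):
        arr = np.zeros((16, 32, 48))
        arr[8, 16, 14] = 200.0
        arr[8, 16, 24] = 200.0  # 2 um apart laterally
        blurred = gaussian_blur_3d(arr, 0.4, voxel_size=CONF)
        blurred *= 200.0 / blurred.max()
        seeds = detect_maxima_3d(blurred, seg_params, full_mask(arr.shape), CONF)
        assert len(seeds) == 2

    def test_low_prominence_shoulder_is_suppressed(self):
        params = SegmentationParams(noise_tolerance=5.0)
        grid = np.zeros((3, 5, 11))
        grid[1, 2, 2] = 100.0
        grid[1, 2, 3] = 97.0  # connecting saddle
        grid[1, 2, 4] = 99.0  # prominence 99 - 97 = 2 < 5
        seeds = detect_maxima_3d(grid, params, full_mask(grid.shape), (0.5, 0.5, 0.5))
        assert [s.position for s in seeds] == [(1, 2, 2)]

    def test_empty_when_nothing_above_threshold(self, seg_params):
        grid = np.full((4, 6, 6), 3.0)
        assert detect_maxima_3d(grid, seg_params, full_mask(grid.shape), CONF) == []

    def test_reference_image_controls_seed_validity(self, seg_params):
        # blurred peak below 16, raw value above: valid with reference only
        grid = np.zeros((3, 7, 7))
        grid[1, 3, 3] = 5.0
        raw = np.zeros((3, 7, 7))
        raw[1, 3, 3] = 200.0
        assert detect_maxima_3d(grid, seg_params, full_mask(grid.shape), CONF) == []
        seeds = detect_maxima_3d(grid, seg_params, full_mask(grid.shape), CONF,
                                 reference=raw)
        assert [s.position for s in seeds] == [(1, 3, 3)]

    @pytest.mark.parametrize("tol", [0.25, 2.0, 6.0])
    def test_matches_brute_force_oracle_on_random_grids(self, rng, tol):
        params = SegmentationParams(noise_tolerance=tol, intensity_threshold=10,
                                    min_distance_xy=0.6, min_distance_z=0.6)
        for trial in range(12):
            shape = tuple(rng.integers(4, 13, 3))
            grid = rng.integers(0, 40, shape).astype(float)
            mask = rng.random(shape) < 0.8
            got = sorted(s.position for s in detect_maxima_3d(
                grid, params, mask, CONF))
            want = brute_force_maxima(grid, mask, tol, 10, 0.6, 0.6, CONF)
            assert got == want

    def test_raising_noise_tolerance_never_increases_seed_count(self, rng):
        for _ in range(10):
            grid = rng.integers(0, 60, (6, 12, 12)).astype(float)
            mask = full_mask(grid.shape)
            prev = np.inf
            for tol in (0.25, 2, 5, 12, 30):
                params = SegmentationParams(noise_tolerance=tol, intensity_threshold=10)
                n = len(detect_maxima_3d(grid, params, mask, CONF))
                assert n <= prev
                prev = n


class TestSegmentBodies:
    def test_one_seed_takes_the_whole_spherical_region(self, seg_params):
        grid = np.zeros((12, 24, 24))
        zz, yy, xx = np.ogrid[:12, :24, :24]
        ball = ((zz - 6) * 0.5) ** 2 + ((yy - 12) * 0.2) ** 2 + ((xx - 12) * 0.2) ** 2 <= 1.0
        grid[ball] = 100.0
        seeds = [SeedPoint((6, 12, 12), 100.0)]
        labels = segment_bodies(grid, grid, seeds, seg_params, full_mask(grid.shape), CONF)
        np.testing.assert_array_equal(labels > 0, ball)
        assert labels.max() == 1

    def test_dumbbell_domain_partitions_at_geodesic_midline(self, seg_params):
        # two lobes joined by a thin bridge; seeds in the lobe centres
        grid = np.zeros((3, 7, 21))
        grid[1, 2:5, 2:7] = 100.0
        grid[1, 3, 7:14] = 100.0  # bridge
        grid[1, 2:5, 14:19] = 100.0
        seeds = [SeedPoint((1, 3, 4), 100.0), SeedPoint((1, 3, 16), 100.0)]
        labels = segment_bodies(grid, grid, seeds, seg_params, full_mask(grid.shape), CONF)
        domain = grid >= seg_params.intensity_threshold
        np.testing.assert_array_equal(labels > 0, domain)  # union = domain
        assert labels[1, 3, 4] == 1 and labels[1, 3, 16] == 2
        assert (labels[1, 3, 7:10] == 1).all() and (labels[1, 3, 11:14] == 2).all()

    def test_bodies_are_disjoint_within_domain_and_contain_their_seed(self, rng, seg_params):
        for _ in range(5):
            grid = rng.integers(0, 60, (6, 14, 14)).astype(float)
            mask = rng.random((6, 14, 14)) < 0.9
            seeds = detect_maxima_3d(grid, SegmentationParams(intensity_threshold=20),
                                     mask, CONF)
            labels = segment_bodies(grid, grid, seeds,
                                    SegmentationParams(intensity_threshold=20,
                                                       min_object_size_um=0.05),
                                    mask, CONF)
            domain = (grid >= 20) & mask
            assert not (labels > 0)[~domain].any()
            for k in range(1, labels.max() + 1):
                assert (labels == k).sum() > 0

    def test_unreachable_domain_voxels_are_dropped(self, seg_params):
        grid = np.zeros((3, 5, 11))
        grid[1, 2, 1:4] = 100.0
        grid[1, 2, 7:10] = 50.0  # disconnected island without a seed
        seeds = [SeedPoint((1, 2, 2), 100.0)]
        labels = segment_bodies(grid, grid, seeds, seg_params, full_mask(grid.shape), CONF)
        assert (labels[1, 2, 7:10] == 0).all()
        assert (labels[1, 2, 1:4] == 1).all()

    def test_seed_outside_domain_is_dropped_with_warning(self, seg_params, caplog):
        grid = np.zeros((3, 5, 5))
        seeds = [SeedPoint((1, 2, 2), 1.0)]
        with caplog.at_level("WARNING"):
            labels = segment_bodies(grid, grid, seeds, seg_params,
                                    full_mask(grid.shape), CONF)
        assert labels.max() == 0
        assert "outside the segmentation domain" in caplog.text

    def test_min_size_filter_semantics(self):
        # one voxel at 0.2 um sampling: mean XY extent 0.2 um
        grid = np.zeros((3, 5, 5))
        grid[1, 2, 2] = 100.0
        seeds = [SeedPoint((1, 2, 2), 100.0)]
        keep = segment_bodies(grid, grid, seeds, SegmentationParams(), full_mask(grid.shape), CONF)
        assert keep.max() == 1
        drop = segment_bodies(grid, grid, seeds,
                              SegmentationParams(min_object_size_um=0.3),
                              full_mask(grid.shape), CONF)
        assert drop.max() == 0

    def test_raising_threshold_never_increases_total_body_volume(self, rng):
        for _ in range(6):
            grid = rng.integers(0, 80, (6, 12, 12)).astype(float)
            mask = full_mask(grid.shape)
            prev = np.inf
            for thr in (10, 20, 35, 60):
                params = SegmentationParams(intensity_threshold=thr,
                                            min_object_size_um=0.05)
                seeds = detect_maxima_3d(grid, params, mask, CONF)
                labels = segment_bodies(grid, grid, seeds, params, mask, CONF)
                vol = int((labels > 0).sum())
                assert vol <= prev
                prev = vol

    def test_watershed_mode_respects_domain_and_seed_count(self, rng):
        params = SegmentationParams(assignment="watershed", intensity_threshold=20,
                                    min_object_size_um=0.05)
        grid = rng.integers(0, 60, (6, 14, 14)).astype(float)
        mask = full_mask(grid.shape)
        seeds = detect_maxima_3d(grid, params, mask, CONF)
        labels = segment_bodies(grid, grid, seeds, params, mask, CONF)
        assert not (labels > 0)[grid < 20].any()
        assert labels.max() <= len(seeds)
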