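"""Nuclei detection: LoG map, dilation maxima, watershed scoring."""

import dataclasses

import numpy as np
import pytest

from lensmap3d.detection import (
    DetectionParams,
    ScaleError,
    detect_nuclei,
    ellipsoid_footprint,
    local_maxima,
    log_likelihood_map,
    segment_and_score,
)
from lensmap3d.stackio import VoxelGrid
from lensmap3d.synthetic import (
    imaging_config,
    match_to_truth,
    mature_config,
    render_stack,
    sample_epithelium,
)

FINE = (1515.2, 1515.2, 2992.0)  # nm, axially resolvable for 4 um nuclei


def two_blob_grid(separation_um, radius_um=4.0, spacing=FINE, amplitude=100.0):
    """Noiseless stack with two Gaussian blobs along x."""
    spacing_um = np.asarray(spacing) / 1000.0
    shape = (
        int(24 / spacing_um[2]) + 1,
        int(30 / spacing_um[1]) + 1,
        int((30 + separation_um) / spacing_um[0]) + 1,
    )
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    sigma = radius_um / 2.0
    data = np.zeros(shape)
    centres = []
    for cx in (15.0, 15.0 + separation_um):
        c = np.array([cx, 15.0, 12.0])
        centres.append(c)
        r2 = (
            ((xx * spacing_um[0] - c[0]) ** 2)
            + ((yy * spacing_um[1] - c[1]) ** 2)
            + ((zz * spacing_um[2] - c[2]) ** 2)
        )
        data += amplitude * np.exp(-r2 / (2 * sigma**2))
    return VoxelGrid(data, tuple(spacing)), np.array(centres)


def brute_force_maxima(likelihood: VoxelGrid, radius_um: float) -> set:
    """Independent maxima oracle: a voxel is a maximum iff no voxel
    within the physical ellipsoid of radius R is larger; connected
    equal-valued plateaus reduced to their lexicographic minimum."""
    data = likelihood.data
    spacing = likelihood.spacing_um
    semi = np.floor(radius_um / spacing).astype(int)  # (x, y, z)
    hits = []
    for z, y, x in np.argwhere(data > 0):
        ok = True
        for dz in range(-semi[2], semi[2] + 1):
            for dy in range(-semi[1], semi[1] + 1):
                for dx in range(-semi[0], semi[0] + 1):
                    if (
                        (dx * spacing[0]) ** 2
                        + (dy * spacing[1]) ** 2
                        + (dz * spacing[2]) ** 2
                    ) > radius_um**2 + 1e-12:
                        continue
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (
                        0 <= zz < data.shape[0]
                        and 0 <= yy < data.shape[1]
                        and 0 <= xx < data.shape[2]
                    ):
                        continue
                    if data[zz, yy, xx] > data[z, y, x]:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            hits.append((z, y, x))
    # plateau reduction: keep lexicographic min of 26-connected equal groups
    hits_set = set(hits)
    reduced = set()
    seen = set()
    for h in sorted(hits_set):
        if h in seen:
            continue
        stack, group = [h], []
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            group.append(cur)
            cz, cy, cx = cur
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        nb = (cz + dz, cy + dy, cx + dx)
                        if (
                            nb in hits_set
                            and nb not in seen
                            and likelihood.data[nb] == likelihood.data[cur]
                        ):
                            stack.append(nb)
        reduced.add(min(group))
    return reduced


class TestLoG:
    def test_constant_image_gives_zero_response(self):
        grid = VoxelGrid(np.full((6, 10, 10), 7.0), FINE)
        resp = log_likelihood_map(grid, 4.0)
        np.testing.assert_allclose(resp.data, 0.0, atol=1e-9)

    def test_response_is_linear_in_intensity(self, rng):
        grid = VoxelGrid(rng.random((6, 12, 12)), FINE)
        double = VoxelGrid(2.0 * grid.data, FINE)
        np.testing.assert_allclose(
            log_likelihood_map(double, 4.0).data,
            2.0 * log_likelihood_map(grid, 4.0).data,
            rtol=1e-9,
            atol=1e-12,
        )

    def test_single_nucleus_argmax_at_planted_centre(self):
        grid, centres = two_blob_grid(separation_um=0.0)  # one doubled blob
        resp = log_likelihood_map(grid, 4.0)
        argmax = np.unravel_index(np.argmax(resp.data), resp.data.shape)
        planted = grid.physical_to_voxel(centres[0])
        np.testing.assert_allclose(argmax, planted, atol=0.6)

    def test_unresolvable_scale_rejected(self):
        grid = VoxelGrid(np.zeros((4, 8, 8)), (1515.2, 1515.2, 5977.2))
        with pytest.raises(ScaleError, match="unresolvable"):
            log_likelihood_map(grid, 4.0)


class TestLocalMaxima:
    def test_matches_brute_force_oracle_on_small_images(self, rng):
        """Dilation-equality maxima agree with the direct neighborhood
        scan on random smooth images up to 32^3."""
        from scipy import ndimage

        for _ in range(3):
            raw = rng.normal(size=(10, 20, 20))
            data = ndimage.gaussian_filter(raw, 1.2)
            lik = VoxelGrid(data, (1000.0, 1000.0, 2000.0))
            ours = {tuple(c) for c in local_maxima(lik, 3.0)}
            assert ours == brute_force_maxima(lik, 3.0)

    def test_two_blobs_two_maxima(self):
        grid, centres = two_blob_grid(separation_um=16.0)
        resp = log_likelihood_map(grid, 4.0)
        peaks = local_maxima(resp, 4.0)
        assert len(peaks) == 2
        planted = np.array([grid.physical_to_voxel(c) for c in centres])
        found = peaks[np.argsort(peaks[:, 2])]
        np.testing.assert_allclose(found, planted[np.argsort(planted[:, 2])], atol=0.6)

    def test_zero_likelihood_gives_no_maxima(self):
        lik = VoxelGrid(np.zeros((6, 8, 8)), FINE)
        assert len(local_maxima(lik, 4.0)) == 0

    def test_footprint_is_anisotropy_corrected(self):
        fp = ellipsoid_footprint(4.0, np.array([1.5152, 1.5152, 2.992]))
        assert fp.shape[0] < fp.shape[1] == fp.shape[2]


class TestSegmentation:
    def test_isolated_ball_is_circular(self):
        """A discretized solid ball at isotropic spacing scores >= 0.9."""
        spacing = (1515.2, 1515.2, 1515.2)
        s = 1.5152
        n = 17
        ax = (np.arange(n) - n // 2) * s
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = (xx**2 + yy**2 + zz**2) <= 6.0**2
        grid = VoxelGrid(np.where(ball, 100.0, 0.0), spacing)
        params = DetectionParams(radius_um=6.0, mask_threshold=50.0)
        _, scores = segment_and_score(grid, [(n // 2, n // 2, n // 2)], params)
        assert len(scores) == 1
        assert scores.circularity.iloc[0] >= 0.9

    def test_line_region_is_degenerate(self):
        data = np.zeros((5, 5, 40))
        data[2, 2, 5:35] = 100.0
        grid = VoxelGrid(data, (1515.2, 1515.2, 1515.2))
        params = DetectionParams(radius_um=2.0, mask_threshold=50.0)
        _, scores = segment_and_score(grid, [(2, 2, 20)], params)
        assert scores.circularity.iloc[0] < 0.2

    def test_overlapping_blobs_split_by_watershed(self):
        radius = 4.0
        grid, centres = two_blob_grid(separation_um=1.5 * radius, radius_um=radius)
        seeds = [tuple(np.round(grid.physical_to_voxel(c)).astype(int)) for c in centres]
        params = DetectionParams(radius_um=radius, mask_threshold=20.0)
        labels, scores = segment_and_score(grid, seeds, params)
        assert len(scores) == 2
        for c, (_, row) in zip(centres, scores.iterrows()):
            region = np.argwhere(labels == row.label)
            w = grid.data[region[:, 0], region[:, 1], region[:, 2]]
            centroid = grid.voxel_to_physical(
                (region * w[:, None]).sum(axis=0) / w.sum()
            )
            assert np.linalg.norm(centroid - c) <= radius / 2

    def test_seed_outside_mask_dropped(self):
        data = np.zeros((5, 8, 8))
        data[2, 4, 4] = 100.0
        grid = VoxelGrid(data, FINE)
        params = DetectionParams(radius_um=4.0, mask_threshold=50.0)
        _, scores = segment_and_score(grid, [(0, 0, 0), (2, 4, 4)], params)
        assert list(scores.seed_index) == [1]


@pytest.fixture(scope="module")
def mini():
    cfg = imaging_config(mature_config(seed=2))
    truth = sample_epithelium(cfg)
    grid, offset = render_stack(truth)
    return cfg, truth, grid, offset


class TestDetectPipeline:
    def test_recall_and_precision_on_phantom(self, mini):
        cfg, truth, grid, offset = mini
        det = detect_nuclei(grid, DetectionParams(radius_um=3.5))
        m = match_to_truth(
            det[["x_um", "y_um", "z_um"]].to_numpy(),
            truth.true_xyz() - offset,
            radius=3.5,
        )
        assert m["precision"] >= 0.9
        assert m["recall"] >= 0.9

    def test_thresholds_are_monotone(self, mini):
        _, _, grid, _ = mini
        base = len(detect_nuclei(grid, DetectionParams(radius_um=3.5)))
        higher_int = len(
            detect_nuclei(
                grid, DetectionParams(radius_um=3.5, intensity_threshold="q99.5")
            )
        )
        higher_circ = len(
            detect_nuclei(
                grid, DetectionParams(radius_um=3.5, circularity_threshold=0.8)
            )
        )
        assert higher_int <= base
        assert higher_circ <= base

    def test_perfect_circularity_threshold_empties_result(self, mini):
        _, _, grid, _ = mini
        det = detect_nuclei(
            grid, DetectionParams(radius_um=3.5, circularity_threshold=1.0)
        )
        assert len(det) == 0

    def test_noise_only_stack_yields_no_spurious_nuclei(self):
        rng = np.random.default_rng(99)
        data = 10.0 + rng.normal(0.0, 2.0, size=(48, 160, 160)).astype(np.float32)
        grid = VoxelGrid(data, FINE)
        det = detect_nuclei(grid, DetectionParams(radius_um=3.5))
        # contract: <= 1 spurious detection per 1e7 voxels
        assert len(det) <= max(1, data.size // 10**7)

    def test_translation_equivariance_whole_voxels(self):
        grid, centres = two_blob_grid(separation_um=20.0)
        params = DetectionParams(radius_um=4.0, intensity_threshold=20.0,
                                 mask_threshold=20.0)
        det = detect_nuclei(grid, params)
        shift = (1, 2, 3)  # voxels (z, y, x)
        shifted = VoxelGrid(np.roll(grid.data, shift, axis=(0, 1, 2)), grid.spacing_nm)
        det2 = detect_nuclei(shifted, params)
        assert len(det) == len(det2) == 2
        delta_um = shifted.voxel_to_physical(shift) - shifted.voxel_to_physical((0, 0, 0))
        a = det[["x_um", "y_um", "z_um"]].to_numpy()
        b = det2[["x_um", "y_um", "z_um"]].to_numpy()
        np.testing.assert_allclose(
            np.sort(b, axis=0), np.sort(a + delta_um, axis=0), atol=1e-6
        )
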