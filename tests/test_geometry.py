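import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmbdetect.candidates import (
    MicrobleedCandidate,
    RoiNeighborhood,
    Status,
    extract_neighborhood,
)
from cmbdetect.config import CutoffConfig
from cmbdetect.geometry import (
    apply_cutoffs,
    blob_compactness,
    blob_perimeter_voxels,
    blob_volume,
    central_blob,
    compute_features,
    frangi_vesselness,
    hessian_field,
    image_entropy,
    mip,
    sweep_threshold,
)
from cmbdetect.phantom import PhantomSpec, generate_phantom
from cmbdetect.volume_io import resample_volume


def entropy_oracle(grid, n_bins=256):
    """Brute-force reference: explicit histogram + log loop."""
    a = np.asarray(grid, float).ravel()
    mn, mx = a.min(), a.max()
    if mx == mn:
        return 0.0
    idx = np.rint((a - mn) / (mx - mn) * (n_bins - 1)).astype(int)
    e = 0.0
    for count in np.bincount(idx, minlength=n_bins):
        if count:
            p = count / a.size
            e -= p * math.log2(p)
    return e


class TestImageEntropy:
    def test_constant_grid_is_zero_bits(self):
        assert image_entropy(np.full((8, 8, 8), 3.0)) == 0.0

    def test_equiprobable_256_levels_is_eight_bits(self):
        grid = np.tile(np.arange(256.0), 4).reshape(32, 32)
        assert image_entropy(grid, 256) == pytest.approx(8.0, abs=1e-12)

    def test_half_half_binary_is_one_bit(self):
        grid = np.zeros((4, 4, 4))
        grid[:2] = 1.0
        assert image_entropy(grid) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.normal(size=(9, 7, 5))
        assert image_entropy(grid) == pytest.approx(
            entropy_oracle(grid), abs=1e-12
        )

    def test_permutation_invariant(self, rng):
        grid = rng.normal(size=(8, 8, 8))
        shuffled = rng.permutation(grid.ravel()).reshape(grid.shape)
        assert image_entropy(shuffled) == pytest.approx(
            image_entropy(grid), abs=1e-12
        )

    def test_bounded_by_log2_bins(self, rng):
        grid = rng.normal(size=(16, 16))
        e = image_entropy(grid, 64)
        assert 0 <= e <= 6.0


class TestMip:
    def test_constant_roi_projects_constant(self):
        assert np.all(mip(np.full((5, 5, 5), 2.0)) == 2.0)

    def test_single_bright_voxel_survives(self):
        grid = np.zeros((5, 5, 5))
        grid[1, 2, 3] = 9.0
        out = mip(grid)
        assert out[1, 2] == 9.0
        assert out.sum() == 9.0

    def test_matches_numpy_max_on_phantom_roi(self, noisy_phantom):
        grid = resample_volume(noisy_phantom.scan, 3, "intensity").intensities
        roi = grid[:51, :51, :25]
        np.testing.assert_array_equal(mip(roi), roi.max(axis=2))


class TestHessian:
    def test_linear_ramp_has_zero_hessian(self):
        x, y, z = np.mgrid[0:9, 0:9, 0:9].astype(float)
        field = hessian_field(2 * x - 3 * y + z)
        interior = field.hessian[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(interior, 0.0, atol=1e-9)

    def test_quadratic_bowl_gives_diag_two(self):
        x, y, z = np.mgrid[0:9, 0:9, 0:9].astype(float)
        field = hessian_field(x**2 + y**2 + z**2)
        interior = field.hessian[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(
            interior, np.broadcast_to(np.diag([2.0, 2.0, 2.0]), interior.shape),
            atol=1e-9,
        )

    def test_hessian_is_symmetric(self, rng):
        field = hessian_field(rng.normal(size=(7, 7, 7)))
        np.testing.assert_allclose(
            field.hessian, np.swapaxes(field.hessian, -1, -2), atol=1e-9
        )

    def test_eigenvalues_sorted_by_magnitude(self, rng):
        field = hessian_field(rng.normal(size=(6, 6, 6)))
        mags = np.abs(field.eigenvalues)
        assert np.all(np.diff(mags, axis=-1) >= -1e-12)

    def test_axis_swap_consistency(self, rng):
        grid = rng.normal(size=(7, 7, 7))
        f1 = hessian_field(grid)
        f2 = hessian_field(np.swapaxes(grid, 0, 1))
        np.testing.assert_allclose(
            np.swapaxes(f2.eigenvalues, 0, 1), f1.eigenvalues, atol=1e-6
        )


def sphere_and_cylinder_rois(noise=0.0, seed=0, tube_radius_mm=1.4):
    """Noise-free dark sphere vs dark z-axis cylinder at equal contrast."""
    spec_s = PhantomSpec(n_spheres=1, sphere_radius_mm=(1.4, 1.4),
                         noise_sigma=noise, seed=seed)
    spec_t = PhantomSpec(n_spheres=0, n_tubes=1, tube_radius_mm=tube_radius_mm,
                         tube_axis="z", noise_sigma=noise, seed=seed)
    out = []
    for spec in (spec_s, spec_t):
        res = generate_phantom(spec)
        vol = resample_volume(res.scan, 3, "intensity")
        if spec.n_spheres:
            center_mm = res.truth.spheres[0].center_mm
        else:
            center_mm = res.truth.tubes[0].point_mm
        c = tuple(
            int(np.clip(round(center_mm[i] / vol.spacing[i]), 0,
                        vol.shape[i] - 1))
            for i in range(3)
        )
        cand = MicrobleedCandidate(center3d=c, member_circles=[])
        out.append(extract_neighborhood(vol.intensities, cand, (51, 51, 25)))
    return out


class TestFrangi:
    def test_bright_blob_has_zero_vesselness(self):
        # bright structure -> negative eigenvalues -> V = 0 at its core
        x, y, z = np.mgrid[0:15, 0:15, 0:15].astype(float)
        d2 = (x - 7) ** 2 + (y - 7) ** 2 + (z - 7) ** 2
        grid = 100.0 * np.exp(-d2 / 8.0)
        field = hessian_field(grid)
        vmap = frangi_vesselness(field)
        assert vmap.v[7, 7, 7] == 0.0

    def test_flat_region_has_zero_vesselness(self):
        vmap = frangi_vesselness(hessian_field(np.full((7, 7, 7), 5.0)))
        np.testing.assert_allclose(vmap.v, 0.0)

    def test_vesselness_bounded_to_unit_interval(self, noisy_phantom):
        grid = resample_volume(noisy_phantom.scan, 3, "intensity").intensities
        vmap = frangi_vesselness(hessian_field(grid[:41, :41, :21]))
        assert vmap.v.min() >= 0.0 and vmap.v.max() <= 1.0

    def test_cylinder_more_vessel_like_than_sphere(self):
        roi_sphere, roi_cyl = sphere_and_cylinder_rois()
        means = []
        for roi in (roi_sphere, roi_cyl):
            vmap = frangi_vesselness(hessian_field(roi.grid))
            # average inside the central structure (12 px in-plane radius)
            x, y, z = np.mgrid[0:51, 0:51, 0:25]
            sel = (x - 25) ** 2 + (y - 25) ** 2 < 10**2
            means.append(float(vmap.v[sel].mean()))
        assert means[1] > means[0]

    def test_axis_swap_leaves_vesselness_unchanged(self, rng):
        grid = rng.normal(size=(9, 9, 9))
        v1 = frangi_vesselness(hessian_field(grid)).v
        v2 = frangi_vesselness(hessian_field(np.swapaxes(grid, 0, 1))).v
        np.testing.assert_allclose(np.swapaxes(v2, 0, 1), v1, atol=1e-6)


class TestCentralBlob:
    def test_selects_component_nearest_center(self):
        v = np.zeros((11, 11, 11))
        v[5, 5, 5] = 1.0  # near center
        v[0, 0, 0] = 1.0  # far corner
        blob = central_blob(v, 0.5, (5, 5, 5))
        assert blob[5, 5, 5] and not blob[0, 0, 0]

    def test_all_zero_map_gives_empty_blob(self):
        assert not central_blob(np.zeros((5, 5, 5)), 0.15, (2, 2, 2)).any()

    def test_blob_masks_nested_across_thresholds(self):
        # solid unimodal response near the center plus a weaker satellite:
        # the central component must shrink monotonically with threshold.
        # (Shell-like maps of hollow voids can re-seed between fragments,
        # so nesting is the contract for solid maps only.)
        x, y, z = np.mgrid[0:31, 0:31, 0:15].astype(float)
        v = np.exp(-((x - 15) ** 2 + (y - 15) ** 2 + (z - 7) ** 2) / 20.0)
        v += 0.5 * np.exp(-((x - 4) ** 2 + (y - 4) ** 2 + (z - 3) ** 2) / 6.0)
        prev = None
        for frac in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6):
            blob = central_blob(v, frac, (15, 15, 7))
            assert blob[15, 15, 7]
            if prev is not None:
                assert np.all(prev | ~blob), "higher-threshold blob not nested"
                assert blob.sum() <= prev.sum()
            prev = blob

    def test_blob_equals_flood_fill_oracle(self, rng):
        v = rng.random((9, 9, 9))
        v[v < 0.6] = 0.0
        blob = central_blob(v, 0.3, (4, 4, 4))
        if not blob.any():
            return
        # oracle: BFS flood fill over 26-neighborhood from the same seed
        mask = v >= 0.3 * v.max()
        coords = np.argwhere(mask)
        d2 = ((coords - 4) ** 2).sum(axis=1)
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
        seed = tuple(coords[order[0]])
        seen = {seed}
        frontier = [seed]
        while frontier:
            x, y, z = frontier.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        n = (x + dx, y + dy, z + dz)
                        if (
                            n not in seen
                            and all(0 <= n[i] < 9 for i in range(3))
                            and mask[n]
                        ):
                            seen.add(n)
                            frontier.append(n)
        oracle = np.zeros_like(mask)
        for p in seen:
            oracle[p] = True
        np.testing.assert_array_equal(blob, oracle)


class TestBlobMeasures:
    def test_empty_blob_has_zero_volume(self):
        assert blob_volume(np.zeros((4, 4, 4), bool)) == 0

    def test_cube_volume_is_count(self):
        m = np.zeros((6, 6, 6), bool)
        m[1:3, 1:3, 1:3] = True
        assert blob_volume(m) == 8

    def test_random_mask_volume_matches_sum(self, rng):
        m = rng.random((7, 7, 7)) > 0.7
        assert blob_volume(m) == int(m.sum())

    def test_single_voxel_compactness_is_one(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert blob_compactness(m) == pytest.approx(1.0)

    def test_2x2x2_cube_compactness(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert blob_compactness(m) == pytest.approx(64 / 8)

    def test_5x5x5_cube_compactness(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        assert blob_perimeter_voxels(m) == 98
        assert blob_compactness(m) == pytest.approx(98**2 / 125)

    def test_empty_blob_compactness_undefined(self):
        with pytest.raises(ValueError):
            blob_compactness(np.zeros((3, 3, 3), bool))


class TestComputeFeatures:
    def test_constant_roi_gives_trivial_features(self, config):
        roi = RoiNeighborhood(np.full((51, 51, 25), 10.0), (0, 0, 0))
        f = compute_features(roi, config)
        assert f.entropy3d == 0.0
        assert f.entropy2d_mip == 0.0
        assert f.blob_volume == 0
        assert f.blob_compactness == 0.0

    def test_clutter_raises_entropy(self, noisy_phantom, config):
        # a microbleed ROI has moderate entropy; overlaying high-gradient
        # ripple clutter (fold-like texture) must raise it
        vol = resample_volume(noisy_phantom.scan, 3, "intensity")
        s = noisy_phantom.truth.spheres[0]
        c = tuple(int(round(s.center_mm[i] / vol.spacing[i])) for i in range(3))
        cand = MicrobleedCandidate(center3d=c, member_circles=[])
        roi = extract_neighborhood(vol.intensities, cand, (51, 51, 25))
        x, y, z = np.mgrid[0:51, 0:51, 0:25].astype(float)
        ripple = 150.0 * np.sin(x / 1.5) * np.sin(y / 1.5)
        cluttered = RoiNeighborhood(roi.grid + ripple, (0, 0, 0))
        f0 = compute_features(roi, config)
        f1 = compute_features(cluttered, config)
        assert f1.entropy3d > f0.entropy3d

    def test_features_invariant_to_intensity_offset(self, noisy_phantom, config):
        grid = resample_volume(noisy_phantom.scan, 3, "intensity").intensities
        roi = RoiNeighborhood(grid[10:61, 10:61, 0:25].copy(), (0, 0, 0))
        shifted = RoiNeighborhood(roi.grid + 500.0, (0, 0, 0))
        f0 = compute_features(roi, config)
        f1 = compute_features(shifted, config)
        assert f1.entropy3d == pytest.approx(f0.entropy3d, abs=1e-9)
        assert f1.entropy2d_mip == pytest.approx(f0.entropy2d_mip, abs=1e-9)
        assert f1.blob_volume == f0.blob_volume
        assert f1.blob_compactness == pytest.approx(f0.blob_compactness)


class TestApplyCutoffs:
    def _cand(self):
        return MicrobleedCandidate((10, 10, 10), [])

    def _feats(self, **kw):
        from cmbdetect.geometry import GeometricFeatures

        base = dict(
            entropy3d=5.0,
            entropy2d_mip=5.0,
            blob_volume=100,
            blob_compactness=50.0,
            blob_threshold_frac=0.15,
        )
        base.update(kw)
        return GeometricFeatures(**base)

    def test_value_exactly_at_cutoff_is_kept(self, config):
        cand = self._cand()
        apply_cutoffs(cand, self._feats(entropy3d=config.entropy3d_max["SWI"]),
                      config, "SWI")
        assert cand.status == Status.ACCEPTED

    def test_rejection_order_is_fixed(self, config):
        cand = self._cand()
        feats = self._feats(entropy3d=99.0, entropy2d_mip=99.0)
        apply_cutoffs(cand, feats, config, "SWI")
        assert cand.status == Status.REJECTED_ENTROPY3D

    def test_oversized_blob_rejected(self, config):
        cand = self._cand()
        apply_cutoffs(
            cand,
            self._feats(blob_volume=int(config.blob_volume_max["SWI"]) + 1),
            config,
            "SWI",
        )
        assert cand.status == Status.REJECTED_BLOB_VOLUME

    def test_compactness_rejection(self, config):
        cand = self._cand()
        apply_cutoffs(
            cand,
            self._feats(blob_compactness=config.compactness_max["SWI"] + 1),
            config,
            "SWI",
        )
        assert cand.status == Status.REJECTED_BLOB_COMPACTNESS

    def test_all_inside_bounds_accepted(self, config):
        cand = self._cand()
        apply_cutoffs(cand, self._feats(), config, "SWI")
        assert cand.status == Status.ACCEPTED

    def test_upstream_rejection_never_overwritten(self, config):
        cand = self._cand()
        cand.status = Status.REJECTED_CSF
        apply_cutoffs(cand, self._feats(entropy3d=99.0), config, "SWI")
        assert cand.status == Status.REJECTED_CSF


class TestSweepThreshold:
    def _rois(self, noise=0.0):
        # vessel mimic at the generator's default caliber (thinner than the
        # microbleed, as in real anatomy)
        roi_sphere, roi_cyl = sphere_and_cylinder_rois(
            noise=noise, tube_radius_mm=0.8
        )
        return [roi_sphere, roi_cyl], [True, False]

    def test_blob_volume_monotone_in_threshold(self):
        # asserted on the solid (tube) response: the blob of a solid map
        # shrinks monotonically with threshold, whereas the shell-like map
        # of a hollow void can re-seed between fragments
        rois, labels = self._rois()
        table = sweep_threshold(rois, labels, [0.1, 0.6])
        fp = table.set_index("frac")["fp_volume_max"]
        assert fp[0.1] >= fp[0.6]

    def test_range_endpoints_evaluated(self):
        rois, labels = self._rois()
        table = sweep_threshold(rois, labels, [0.1, 0.6])
        assert set(table["frac"]) == {0.1, 0.6}

    def test_sphere_blobs_smaller_than_tube_blobs(self):
        rois, labels = self._rois()
        table = sweep_threshold(rois, labels, [0.15])
        row = table.iloc[0]
        assert row["tp_volume_max"] < row["fp_volume_min"]

    def test_empty_label_set_rejected(self):
        with pytest.raises(ValueError):
            sweep_threshold([], [], [0.1])
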