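"""Cube dissection, local density, surface roughness and derived profiles."""

import numpy as np
import pandas as pd
import pytest

from biofilmcubes.image_io import BinaryMask, ImageStack
from biofilmcubes.quantification import (
    SurfaceMap,
    annotate_local_density,
    classify_cubes,
    density_z_profile,
    dissect,
    expression_vs_density,
    expression_z_profile,
    height_map,
    local_density,
    normalize_channel,
    roughness_map,
    timer_ratio,
)


def brute_force_ball_fraction(mask: BinaryMask, point, radius):
    """Independent oracle: explicit loop over every voxel centre."""
    s = mask.spacing_um
    n_fg = n_all = 0
    nz, ny, nx = mask.voxels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                d2 = (
                    ((z + 0.5) * s - point[0]) ** 2
                    + ((y + 0.5) * s - point[1]) ** 2
                    + ((x + 0.5) * s - point[2]) ** 2
                )
                if d2 <= radius**2:
                    n_all += 1
                    if mask.voxels[z, y, x]:
                        n_fg += 1
    return n_fg / n_all if n_all else 0.0


def _uniform_stack(shape, value=100.0, channels=("constitutive",), spacing=1.0):
    vox = np.full((len(channels),) + shape, float(value))
    return ImageStack(vox, (spacing,) * 3, list(channels))


class TestDissect:
    def test_full_cube_grid_forced_arithmetic(self):
        mask = BinaryMask(np.ones((10, 10, 10), dtype=bool), 1.0)
        cubes = dissect(mask, _uniform_stack((10, 10, 10)), cube_side_vox=5)
        assert len(cubes) == 8
        assert (cubes.occupancy_vox == 125).all()
        assert (cubes.mean_constitutive == 100.0).all()
        # centres of mass sit at the cubes' geometric centres
        expected = {2.5, 7.5}
        assert set(np.round(cubes.com_z_um, 9)) == expected
        assert set(np.round(cubes.com_x_um, 9)) == expected

    def test_all_background_gives_empty_table(self):
        mask = BinaryMask(np.zeros((10, 10, 10), dtype=bool), 1.0)
        cubes = dissect(mask, _uniform_stack((10, 10, 10)), cube_side_vox=5)
        assert cubes.empty

    def test_single_voxel_cube(self):
        vox = np.zeros((6, 6, 6), dtype=bool)
        vox[1, 2, 3] = True
        raw = _uniform_stack((6, 6, 6), value=7.0)
        cubes = dissect(BinaryMask(vox, 1.0), raw, cube_side_vox=5)
        assert len(cubes) == 1
        row = cubes.iloc[0]
        assert row.occupancy_vox == 1
        assert row.mean_constitutive == 7.0
        assert (row.com_z_um, row.com_y_um, row.com_x_um) == (1.5, 2.5, 3.5)

    def test_occupancy_conservation_on_random_masks(self, rng):
        for _ in range(5):
            shape = tuple(int(v) for v in rng.integers(6, 18, 3))
            vox = rng.random(shape) < 0.3
            mask = BinaryMask(vox, 0.5)
            cubes = dissect(mask, _uniform_stack(shape, spacing=0.5), cube_side_vox=5)
            assert cubes.occupancy_vox.sum() == vox.sum()

    def test_partial_border_cubes_retained_with_true_counts(self):
        mask = BinaryMask(np.ones((7, 5, 5), dtype=bool), 1.0)
        cubes = dissect(mask, _uniform_stack((7, 5, 5)), cube_side_vox=5)
        assert len(cubes) == 2
        assert sorted(cubes.occupancy_vox) == [50, 125]

    def test_shape_mismatch_rejected(self):
        mask = BinaryMask(np.ones((6, 6, 6), dtype=bool), 1.0)
        with pytest.raises(ValueError, match="shape"):
            dissect(mask, _uniform_stack((5, 6, 6)), cube_side_vox=5)


class TestLocalDensity:
    def test_full_foreground_interior_point_is_one(self):
        mask = BinaryMask(np.ones((20, 20, 20), dtype=bool), 1.0)
        assert local_density(mask, (10.0, 10.0, 10.0), 3.0) == 1.0

    def test_all_background_is_zero(self):
        mask = BinaryMask(np.zeros((20, 20, 20), dtype=bool), 1.0)
        assert local_density(mask, (10.0, 10.0, 10.0), 3.0) == 0.0

    def test_half_space_boundary_point_is_half(self):
        vox = np.zeros((24, 24, 24), dtype=bool)
        vox[:12] = True  # foreground below the z = 12 um plane
        mask = BinaryMask(vox, 1.0)
        d = local_density(mask, (12.0, 12.0, 12.0), 3.0)
        # one voxel shell out of a radius-3 ball is about 1/3 of its volume
        assert abs(d - 0.5) <= 1.0 / 3.0
        assert d == brute_force_ball_fraction(mask, (12.0, 12.0, 12.0), 3.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(int(v) for v in rng.integers(8, 16, 3))
        mask = BinaryMask(rng.random(shape) < 0.4, float(rng.choice([0.5, 1.0])))
        s = mask.spacing_um
        point = tuple(rng.uniform(0, np.array(shape) * s))
        radius = float(rng.uniform(1.0, 3.0))
        assert local_density(mask, point, radius) == brute_force_ball_fraction(
            mask, point, radius
        )

    def test_edge_normalization_uses_in_bounds_voxels_only(self):
        # full foreground: density at a corner must still be 1, because the
        # denominator counts only in-bounds centres
        mask = BinaryMask(np.ones((10, 10, 10), dtype=bool), 1.0)
        assert local_density(mask, (0.5, 0.5, 0.5), 3.0) == 1.0

    def test_nonpositive_radius_rejected(self):
        mask = BinaryMask(np.ones((4, 4, 4), dtype=bool), 1.0)
        with pytest.raises(ValueError):
            local_density(mask, (2, 2, 2), 0.0)


class TestSurface:
    def test_slab_height_voxel_center_convention(self, slab_mask):
        surface = height_map(slab_mask)
        np.testing.assert_allclose(surface.height_um, 19.5)

    def test_empty_mask_all_undefined(self):
        mask = BinaryMask(np.zeros((5, 6, 6), dtype=bool), 1.0)
        assert np.isnan(height_map(mask).height_um).all()

    def test_single_column_height_scaled_by_spacing(self):
        vox = np.zeros((10, 4, 4), dtype=bool)
        vox[7, 1, 2] = True
        vox[3, 1, 2] = True  # topmost wins
        surface = height_map(BinaryMask(vox, 0.5))
        assert surface.height_um[1, 2] == pytest.approx((7 + 0.5) * 0.5)

    def test_flat_slab_roughness_zero(self, slab_mask):
        surface = roughness_map(height_map(slab_mask), window_px=5)
        np.testing.assert_allclose(surface.roughness_um, 0.0)

    def test_step_roughness_matches_direct_sd(self):
        vox = np.zeros((25, 9, 30), dtype=bool)
        vox[:10, :, :15] = True
        vox[:20, :, 15:] = True
        surface = roughness_map(height_map(BinaryMask(vox, 1.0)), window_px=5)
        # window fully on one side of the step: constant height, roughness 0
        assert surface.roughness_um[4, 5] == pytest.approx(0.0)
        # window centred on the step edge: explicit SD of the window values
        heights = surface.height_um[2:7, 13:18]
        assert surface.roughness_um[4, 15] == pytest.approx(heights.std(ddof=1))
        assert surface.roughness_um[4, 15] > 0

    def test_translation_invariance_in_height(self, rng):
        h = rng.random((15, 15)) * 10
        a = roughness_map(SurfaceMap(h, 1.0), window_px=5).roughness_um
        b = roughness_map(SurfaceMap(h + 42.0, 1.0), window_px=5).roughness_um
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_window_with_fewer_than_two_defined_is_nan(self):
        h = np.full((9, 9), np.nan)
        h[4, 4] = 5.0
        rough = roughness_map(SurfaceMap(h, 1.0), window_px=3).roughness_um
        assert np.isnan(rough[4, 4])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            roughness_map(SurfaceMap(np.zeros((5, 5)), 1.0), window_px=4)


def _cube_df(**cols):
    n = max(len(v) for v in cols.values())
    base = {
        "gz": np.zeros(n, dtype=int),
        "gy": np.zeros(n, dtype=int),
        "gx": np.arange(n),
        "occupancy_vox": np.ones(n, dtype=int),
        "com_z_um": np.zeros(n),
        "com_y_um": np.zeros(n),
        "com_x_um": np.zeros(n),
    }
    base.update({k: np.asarray(v, dtype=float) for k, v in cols.items()})
    return pd.DataFrame(base)


class TestProfiles:
    def test_single_bin_mean(self):
        cubes = _cube_df(local_density=[0.7, 0.7, 0.7], com_z_um=[0.5, 1.0, 1.5])
        profile = density_z_profile(cubes, z_bin_um=2.0)
        assert profile.values.tolist() == pytest.approx([0.7])
        assert profile.n_per_bin.tolist() == [3]

    def test_empty_table_all_undefined(self):
        cubes = _cube_df(local_density=[]).iloc[:0]
        profile = density_z_profile(cubes, z_bin_um=2.0)
        assert np.isnan(profile.values).all()

    def test_two_bin_means(self):
        cubes = _cube_df(
            local_density=[0.2, 0.4, 0.8], com_z_um=[0.5, 1.5, 3.0]
        )
        profile = density_z_profile(cubes, z_bin_um=2.0)
        np.testing.assert_allclose(profile.values, [0.3, 0.8])

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            density_z_profile(_cube_df(local_density=[0.1]), z_bin_um=0.0)


class TestNormalization:
    def test_simple_ratio(self):
        cubes = _cube_df(mean_curli=[50.0], mean_constitutive=[100.0])
        ratio = normalize_channel(cubes, "curli", "constitutive")
        assert ratio.tolist() == [0.5]

    def test_zero_reference_excluded_and_counted(self, caplog):
        cubes = _cube_df(mean_curli=[50.0, 10.0], mean_constitutive=[100.0, 0.0])
        with caplog.at_level("INFO", logger="biofilmcubes.quantification"):
            ratio = normalize_channel(cubes, "curli", "constitutive")
        assert len(ratio) == 1
        assert "excluded 1" in caplog.text

    def test_self_ratio_is_identity(self):
        cubes = _cube_df(mean_curli=[3.0, 9.0, 27.0])
        assert (normalize_channel(cubes, "curli", "curli") == 1.0).all()

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            normalize_channel(_cube_df(mean_curli=[1.0]), "curli", "gfp")

    def test_timer_ratio_arithmetic(self):
        cubes = _cube_df(mean_timer_orange=[30.0, 60.0], mean_timer_green=[60.0, 60.0])
        np.testing.assert_allclose(timer_ratio(cubes), [0.5, 1.0])


class TestExpressionHistograms:
    def test_single_value_single_bin(self):
        cubes = _cube_df(
            local_density=[1.0] * 5,
            mean_curli=[20.0] * 5,
            mean_constitutive=[10.0] * 5,
        )
        hist = expression_vs_density(cubes, "curli", "constitutive",
                                     density_bins=4, value_bins=4)
        assert hist.counts.sum() == 5
        assert (hist.counts == 5).sum() == 1

    def test_counts_conserved(self, rng):
        n = 200
        cubes = _cube_df(
            local_density=rng.random(n),
            com_z_um=rng.random(n) * 30,
            mean_curli=rng.random(n) * 100,
            mean_constitutive=rng.random(n) * 100 + 1,
        )
        for fn in (expression_vs_density, expression_z_profile):
            hist = fn(cubes, "curli", "constitutive")
            assert hist.counts.sum() == n

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            expression_vs_density(
                _cube_df(local_density=[]).iloc[:0], "curli", "constitutive"
            )


class TestClassifyCubes:
    @staticmethod
    def _masks():
        a = np.zeros((5, 5, 10), dtype=bool)
        b = np.zeros((5, 5, 10), dtype=bool)
        a[2, 2, 2] = True  # first cube only
        b[2, 2, 7] = True  # second cube only
        return {"curli": BinaryMask(a, 1.0), "flagella": BinaryMask(b, 1.0)}

    def test_exclusive_overlap_labels(self):
        masks = self._masks()
        merged = BinaryMask(masks["curli"].voxels | masks["flagella"].voxels, 1.0)
        cubes = dissect(merged, _uniform_stack((5, 5, 10)), cube_side_vox=5)
        cubes = classify_cubes(cubes, masks, cube_side_vox=5)
        by_gx = cubes.set_index("gx")
        assert bool(by_gx.loc[0, "positive_curli"]) is True
        assert bool(by_gx.loc[0, "positive_flagella"]) is False
        assert bool(by_gx.loc[1, "positive_flagella"]) is True

    def test_double_overlap_labels_both(self):
        masks = self._masks()
        masks["flagella"].voxels[2, 2, 3] = True  # now also in the first cube
        merged = BinaryMask(masks["curli"].voxels | masks["flagella"].voxels, 1.0)
        cubes = dissect(merged, _uniform_stack((5, 5, 10)), cube_side_vox=5)
        cubes = classify_cubes(cubes, masks, cube_side_vox=5)
        first = cubes.set_index("gx").loc[0]
        assert bool(first.positive_curli) and bool(first.positive_flagella)

    def test_min_overlap_threshold(self):
        masks = self._masks()
        merged = BinaryMask(masks["curli"].voxels | masks["flagella"].voxels, 1.0)
        cubes = dissect(merged, _uniform_stack((5, 5, 10)), cube_side_vox=5)
        cubes = classify_cubes(cubes, masks, cube_side_vox=5, min_overlap_vox=2)
        assert not cubes.positive_curli.any()


class TestAnnotateLocalDensity:
    def test_annotation_matches_pointwise_function(self, rng):
        vox = rng.random((10, 10, 10)) < 0.4
        mask = BinaryMask(vox, 1.0)
        cubes = dissect(mask, _uniform_stack((10, 10, 10)), cube_side_vox=5)
        annotated = annotate_local_density(cubes, mask, radius_um=3.0)
        for _, row in annotated.iterrows():
            expected = local_density(
                mask, (row.com_z_um, row.com_y_um, row.com_x_um), 3.0
            )
            assert row.local_density == expected
        assert annotated.local_density.between(0, 1).all()
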