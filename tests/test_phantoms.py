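"""Phantom generation, augmentation, patch extraction, dataset assembly."""

import numpy as np
import pytest

from pavision.phantoms import (AbsorptionMap, PhantomConfig, augment,
                               build_dataset, extract_patch,
                               generate_branching_phantom, load_dataset_h5,
                               threshold_background)


class TestGenerator:
    def test_deterministic_in_config_and_seed(self):
        cfg = PhantomConfig(seed=42)
        a = generate_branching_phantom(cfg).values
        b = generate_branching_phantom(cfg).values
        np.testing.assert_array_equal(a, b)

    def test_zero_branches_gives_empty_map(self):
        cfg = PhantomConfig(n_primary_branches=0)
        assert not np.any(generate_branching_phantom(cfg).values)

    def test_values_in_unit_interval(self):
        v = generate_branching_phantom(PhantomConfig(seed=3)).values
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_foreground_fraction_in_plausible_band(self):
        # vessel trees should cover a few percent of the field, not fill it
        fracs = [float((generate_branching_phantom(PhantomConfig(seed=s)).values > 0).mean())
                 for s in range(50)]
        assert min(fracs) >= 0.02 and max(fracs) <= 0.25

    def test_contains_near_vertical_structure(self):
        # structure-tensor orientation histogram must include steep segments,
        # otherwise the visibility problem would go unexercised
        from skimage.feature import structure_tensor

        for seed in range(5):
            v = generate_branching_phantom(PhantomConfig(seed=seed)).values
            Azz, Azx, Axx = structure_tensor(v, sigma=2.0, order="rc")
            mask = v > 0.5
            # orientation of the local gradient normal; vessel axis is 90 deg away
            theta = 0.5 * np.arctan2(2 * Azx[mask], Axx[mask] - Azz[mask])
            axis_from_vertical = np.abs(np.degrees(theta))
            assert np.any(axis_from_vertical <= 10.0)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate|16 px"):
            generate_branching_phantom(
                PhantomConfig(field_size_mm=0.4, patch_size_mm=0.4))

    def test_field_must_contain_patch(self):
        with pytest.raises(ValueError):
            PhantomConfig(field_size_mm=4.0, patch_size_mm=5.12)


class TestAugment:
    @pytest.fixture()
    def img(self, rng):
        v = (rng.random((33, 33)) > 0.8) * rng.random((33, 33))
        return AbsorptionMap(v, 40.0)

    def test_zero_rotation_is_identity(self, img):
        np.testing.assert_array_equal(augment(img, ("rotation", {"angle_deg": 0})).values,
                                      img.values)

    def test_mirror_is_involution(self, img):
        once = augment(img, ("mirror", {"axis": "horizontal"}))
        twice = augment(once, ("mirror", {"axis": "horizontal"}))
        np.testing.assert_array_equal(twice.values, img.values)

    def test_rotation_90_maps_single_pixel_correctly(self):
        v = np.zeros((33, 33))
        v[5, 20] = 1.0
        img = AbsorptionMap(v, 40.0)
        out = augment(img, ("rotation", {"angle_deg": 90})).values
        # rotate CCW about the center (16, 16): (r, c) -> (16 - (c-16), 16 + (r-16))
        assert out[16 - (20 - 16), 16 + (5 - 16)] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("spec", [("rotation", {"angle_deg": 17.0}),
                                      ("shear", {"axis": "horizontal", "factor": 0.2}),
                                      ("center_scale", {"factor": 1.3}),
                                      ("mirror", {"axis": "vertical"})])
    def test_shape_and_range_preserved(self, img, spec):
        out = augment(img, spec)
        assert out.values.shape == img.values.shape
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_unknown_transform_rejected(self, img):
        with pytest.raises(ValueError, match="unknown transform"):
            augment(img, ("swirl", {}))


class TestThresholdAndPatch:
    def test_zero_threshold_is_identity(self, rng):
        img = AbsorptionMap(rng.random((20, 20)), 40.0)
        np.testing.assert_array_equal(threshold_background(img, 0.0).values, img.values)

    def test_threshold_above_max_zeroes_everything(self, rng):
        img = AbsorptionMap(rng.random((20, 20)), 40.0)
        assert not np.any(threshold_background(img, 2.0).values)

    def test_ramp_threshold_survivor_count(self):
        ramp = np.tile(np.linspace(0, 1, 101), (5, 1))
        img = AbsorptionMap(ramp, 40.0)
        out = threshold_background(img, 0.5).values
        # exactly the 51 columns with value >= 0.5 survive in each row
        assert int((out > 0).sum()) == 5 * 51

    def test_full_field_patch_is_identity(self, rng):
        v = rng.random((64, 64))
        img = AbsorptionMap(v, 40.0, (-1.26, 2.0))
        center = (-1.26 + 0.04 * 31.5, 2.0 + 0.04 * 31.5)
        out = extract_patch(img, center, 64 * 0.04)
        np.testing.assert_array_equal(out.values, v)

    def test_patch_pixel_count_from_metric_size(self):
        img = AbsorptionMap(np.zeros((256, 256)), 40.0, (-5.1, 0.5))
        center = (-5.1 + 0.04 * 127.5, 0.5 + 0.04 * 127.5)
        out = extract_patch(img, center, 5.12)
        assert out.values.shape == (128, 128)  # 5.12 mm / 40 um

    def test_patch_equals_directly_indexed_subarray(self, rng):
        v = rng.random((64, 64))
        img = AbsorptionMap(v, 40.0, (0.0, 1.0))
        out = extract_patch(img, (0.04 * 11.5, 1.0 + 0.04 * 21.5), 0.32)  # 8 px
        np.testing.assert_array_equal(out.values, v[18:26, 8:16])

    def test_out_of_bounds_patch_rejected(self):
        img = AbsorptionMap(np.zeros((32, 32)), 40.0)
        with pytest.raises(ValueError, match="outside"):
            extract_patch(img, (0.0, 0.0), 1.28)


class TestBuildDataset:
    def test_single_pair_shapes_match(self, tiny_phantom_cfg, tiny_probe):
        ds = build_dataset(1, tiny_phantom_cfg, tiny_probe, seed=3)
        assert ds.inputs.shape == ds.targets.shape == (1, 32, 32)

    def test_rerun_reproducible(self, tiny_phantom_cfg, tiny_probe):
        a = build_dataset(2, tiny_phantom_cfg, tiny_probe, seed=9)
        b = build_dataset(2, tiny_phantom_cfg, tiny_probe, seed=9)
        np.testing.assert_array_equal(a.targets, b.targets)
        np.testing.assert_array_equal(a.inputs, b.inputs)

    def test_split_partition_disjoint_and_exhaustive(self, tiny_phantom_cfg, tiny_probe):
        ds = build_dataset(12, tiny_phantom_cfg, tiny_probe, seed=1,
                           splits={"train": 8, "val": 3, "test": 1})
        allidx = np.concatenate([ds.splits[k] for k in ("train", "val", "test")])
        assert len(allidx) == 12 and len(np.unique(allidx)) == 12

    def test_h5_roundtrip(self, tiny_phantom_cfg, tiny_probe, tmp_path):
        path = str(tmp_path / "ds.h5")
        ds = build_dataset(3, tiny_phantom_cfg, tiny_probe, seed=2,
                           splits={"train": 2, "val": 1}, out_path=path)
        back = load_dataset_h5(path)
        x1, y1 = ds.subset("train")
        x2, y2 = back.subset("train")
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)
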