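"""CT I/O and the preprocessing chain."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nodseg.preprocess import (CTVolume, FormatError, NoduleAnnotation,
                               apply_lung_mask, clip_hu, crop_roi,
                               extract_lung_mask, load_annotations,
                               load_volume, normalize_volume, preprocess_case,
                               resample_isotropic, save_volume,
                               sphere_mask_from_annotation, world_to_voxel)


def _vol(arr, spacing=(1, 1, 1), origin=(0, 0, 0), domain="HU"):
    return CTVolume(np.asarray(arr, np.float32), spacing, origin, domain)


class TestIO:
    def test_volume_round_trip(self, tmp_path, rng):
        v = _vol(rng.normal(0, 100, (8, 10, 12)), spacing=(2.5, 0.7, 0.7),
                 origin=(-4.0, 1.0, 2.0))
        save_volume(v, tmp_path / "x.mhd")
        back = load_volume(tmp_path / "x.mhd")
        np.testing.assert_array_equal(back.voxels, v.voxels)
        assert back.spacing == (2.5, 0.7, 0.7)
        assert back.origin == (-4.0, 1.0, 2.0)

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_volume(tmp_path / "nope.mhd")

    def test_annotation_parsing(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("seriesuid,coordX,coordY,coordZ,diameter_mm\n"
                     "s1,10.0,-20.0,30.0,6.0\n")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (a,) = load_annotations(p)
        assert a.series_id == "s1"
        assert a.center_world == (10.0, -20.0, 30.0)
        assert a.diameter_mm == 6.0

    def test_empty_csv_and_missing_column(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("seriesuid,coordX,coordY,coordZ,diameter_mm\n")
        assert load_annotations(p) == []
        q = tmp_path / "bad.csv"
        q.write_text("seriesuid,coordX,coordY,coordZ\ns1,0,0,0\n")
        with pytest.raises(FormatError, match="diameter_mm"):
            load_annotations(q)

    def test_negative_diameter_rejected_with_row(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("seriesuid,coordX,coordY,coordZ,diameter_mm\n"
                     "s1,0,0,0,5.0\ns2,0,0,0,-1.0\n")
        with pytest.raises(ValueError, match="row 3"):
            load_annotations(p)


class TestClipNormalize:
    def test_clip_window(self):
        v = _vol([[[-2000, -1000, 0, 600, 3000]]])
        out = clip_hu(v)
        assert out.voxels.ravel().tolist() == [-1000, -1000, 0, 600, 600]

    def test_clip_identity_inside_window(self):
        v = _vol(np.zeros((2, 2, 2)))
        np.testing.assert_array_equal(clip_hu(v).voxels, v.voxels)

    def test_clip_bad_window(self):
        with pytest.raises(ValueError):
            clip_hu(_vol(np.zeros((1, 1, 1))), lo=0, hi=0)

    def test_normalize_two_voxel_map(self):
        out = normalize_volume(_vol([[[-1000.0, 600.0]]]))
        np.testing.assert_allclose(out.voxels.ravel(), [-0.5, 0.5], atol=1e-6)
        assert out.intensity_domain == "normalized"

    def test_normalize_mean_zero_and_bounded(self, rng):
        v = _vol(rng.uniform(-1000, 600, (6, 6, 6)))
        out = normalize_volume(v)
        assert abs(out.voxels.mean()) < 1e-6
        assert out.voxels.min() >= -1.0 and out.voxels.max() <= 1.0

    def test_double_normalization_refused(self):
        v = normalize_volume(_vol(np.zeros((2, 2, 2))))
        with pytest.raises(ValueError):
            normalize_volume(v)


class TestResample:
    def test_shape_arithmetic(self, rng):
        v = _vol(rng.normal(size=(50, 40, 40)), spacing=(2.0, 0.5, 0.5))
        out = resample_isotropic(v)
        assert out.shape == (100, 20, 20)
        assert out.spacing == (1.0, 1.0, 1.0)

    def test_identity_at_target_spacing(self, rng):
        v = _vol(rng.normal(size=(8, 8, 8)))
        np.testing.assert_allclose(resample_isotropic(v).voxels, v.voxels,
                                   atol=1e-6)

    def test_world_extent_preserved(self, rng):
        v = _vol(rng.normal(size=(30, 25, 25)), spacing=(1.7, 0.9, 0.9))
        out = resample_isotropic(v)
        for n_out, n_in, s in zip(out.shape, v.shape, v.spacing):
            assert abs(n_out * 1.0 - n_in * s) <= 1.0

    def test_constant_preserved(self):
        v = _vol(np.full((10, 10, 10), 7.0), spacing=(1.7, 0.8, 0.8))
        out = resample_isotropic(v)
        assert np.allclose(out.voxels, 7.0)

    def test_bad_target(self):
        with pytest.raises(ValueError):
            resample_isotropic(_vol(np.zeros((2, 2, 2))), target_spacing=0)


class TestGeometry:
    def test_world_to_voxel_axis_reorder(self):
        v = _vol(np.zeros((40, 40, 40)))
        ann = NoduleAnnotation("s", (10.0, 20.0, 30.0), 5.0)
        assert world_to_voxel(ann, v) == (30, 20, 10)

    def test_world_to_voxel_origin_shift(self):
        v = _vol(np.zeros((10, 10, 10)), origin=(-5, -5, -5))
        ann = NoduleAnnotation("s", (0.0, 0.0, 0.0), 5.0)
        assert world_to_voxel(ann, v) == (5, 5, 5)

    def test_out_of_bounds_names_annotation(self):
        v = _vol(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="far-away"):
            world_to_voxel(NoduleAnnotation("far-away", (99.0, 0.0, 0.0), 5.0), v)

    def test_crop_interior_matches_subarray(self, rng):
        arr = rng.normal(size=(64, 128, 128)).astype(np.float32)
        v = _vol(arr, domain="normalized")
        m = (arr > 0).astype(np.uint8)
        s = crop_roi(v, m, (32, 64, 64))
        np.testing.assert_array_equal(s.image, arr[27:38, 32:96, 32:96])
        np.testing.assert_array_equal(s.mask, m[27:38, 32:96, 32:96])

    def test_crop_corner_zero_pads(self, rng):
        arr = rng.normal(size=(20, 40, 40)).astype(np.float32) + 5
        v = _vol(arr, domain="normalized")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = crop_roi(v, np.ones_like(arr, np.uint8), (0, 0, 0))
        assert s.image.shape == (11, 64, 64)
        assert np.all(s.image[:5] == 0) and np.all(s.image[:, :32] == 0)
        np.testing.assert_array_equal(s.image[5:, 32:, 32:], arr[:6, :32, :32])

    def test_crop_center_value_contract(self, rng):
        arr = rng.normal(size=(30, 70, 70)).astype(np.float32)
        v = _vol(arr, domain="normalized")
        for c in [(15, 35, 35), (5, 10, 60), (29, 69, 0)]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = crop_roi(v, np.zeros_like(arr, np.uint8), c)
            assert s.image[5, 32, 32] == arr[c]

    def test_sphere_mask_volume_and_symmetry(self):
        v = _vol(np.zeros((40, 40, 40)))
        ann = NoduleAnnotation("s", (20.0, 20.0, 20.0), 6.0)
        m = sphere_mask_from_annotation(ann, v)
        expected = 4 / 3 * np.pi * 3 ** 3
        assert abs(m.sum() - expected) / expected < 0.15
        sub = m[16:25, 16:25, 16:25]           # window centred on the sphere
        np.testing.assert_array_equal(sub, sub[::-1, ::-1, ::-1])

    def test_sphere_mask_subvoxel_diameter(self):
        v = _vol(np.zeros((10, 10, 10)))
        m = sphere_mask_from_annotation(NoduleAnnotation("s", (5.0, 5.0, 5.0), 0.4), v)
        assert m.sum() >= 1 and m[5, 5, 5]


class TestLungMask:
    def test_phantom_lung_overlap(self, solid_case):
        clipped = clip_hu(solid_case.volume)
        mask = extract_lung_mask(clipped)
        lungs = solid_case.lung_label.astype(bool)
        overlap = (mask & lungs).sum() / lungs.sum()
        assert overlap >= 0.95

    def test_morphological_containment(self, solid_case):
        from scipy import ndimage
        clipped = clip_hu(solid_case.volume)
        mask = extract_lung_mask(clipped)
        eroded = ndimage.binary_erosion(solid_case.lung_label.astype(bool))
        dilated = ndimage.binary_dilation(mask, iterations=2)
        assert np.all(dilated[eroded])

    def test_fail_open_on_uniform_air(self):
        v = _vol(np.full((10, 10, 10), -1000.0))
        with pytest.warns(UserWarning, match="all-true"):
            m = extract_lung_mask(v)
        assert m.all()

    def test_apply_mask_fills_background(self):
        v = _vol(np.full((4, 4, 4), 100.0))
        m = np.zeros((4, 4, 4), bool)
        m[1:3] = True
        out = apply_lung_mask(v, m)
        assert np.all(out.voxels[0] == -1000) and np.all(out.voxels[1] == 100)


class TestPipeline:
    def test_deterministic_repeat(self, solid_case):
        s1 = preprocess_case(solid_case.volume, [solid_case.annotation],
                             gt_mask=solid_case.mask)
        s2 = preprocess_case(solid_case.volume, [solid_case.annotation],
                             gt_mask=solid_case.mask)
        assert np.array_equal(s1[0].image, s2[0].image)
        assert np.array_equal(s1[0].mask, s2[0].mask)

    def test_roi_shape_and_nonempty_mask(self, solid_case):
        (s,) = preprocess_case(solid_case.volume, [solid_case.annotation],
                               gt_mask=solid_case.mask)
        assert s.image.shape == (11, 64, 64)
        assert s.mask.sum() > 0 and s.mask[5, 32, 32] == 1
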