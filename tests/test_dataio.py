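"""Crop layout, slicing, COCO round trips and rotation augmentation."""
from __future__ import annotations

import json
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octlayers import (
    PhantomSpec,
    boundaries_to_classmap,
    cut_crops,
    dice,
    generate_phantom,
    read_coco,
    rle_decode,
    rle_encode,
    rotate_augment,
    specific_crop,
    write_coco,
)
from octlayers.dataio import AUXILIARY, MAIN, CropError
from octlayers.phantom import BoundarySet


class TestSpecificCrop:
    def test_nominal_geometry_offsets_and_roles(self):
        crops = specific_crop(1534, 512)
        assert [w.offset for w in crops.windows] == [0, 256, 512, 768, 1022]
        assert [w.role for w in crops.windows] == [MAIN, AUXILIARY, MAIN, AUXILIARY, MAIN]
        assert [w.index for w in crops.windows] == ["A", "D", "B", "E", "C"]

    def test_image_equal_to_crop_gives_single_main_window(self):
        crops = specific_crop(512, 512)
        assert [w.offset for w in crops.windows] == [0]
        assert crops.windows[0].role == MAIN

    def test_flush_final_crop_needs_no_clamp(self):
        crops = specific_crop(1024, 512)
        assert [w.offset for w in crops.windows] == [0, 256, 512]
        assert [w.role for w in crops.windows] == [MAIN, AUXILIARY, MAIN]

    def test_crop_larger_than_image_rejected(self):
        with pytest.raises(CropError):
            specific_crop(500, 512)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(width=st.integers(min_value=64, max_value=256))
    def test_coverage_and_auxiliary_support(self, width):
        """Every column is covered; interior main-crop edges lie in an auxiliary."""
        crop_size = 64
        crops = specific_crop(width, crop_size)
        covered = np.zeros(width, dtype=bool)
        for w in crops.windows:
            covered[w.offset : w.stop] = True
        assert covered.all()
        for i in range(len(crops.windows) - 1):
            assert crops.windows[i + 1].offset < crops.windows[i].stop  # overlap
        for w in crops.mains:
            for edge in (w.offset, w.stop):
                if 0 < edge < width:  # interior boundary of a main crop
                    assert any(a.covers(edge - 1) or a.covers(edge) for a in crops.auxiliaries)


class TestCutCrops:
    def test_pure_slicing_reassembles_source(self, small_phantom):
        bscan, _, _ = small_phantom
        crops = specific_crop(bscan.width, 64)
        parts = cut_crops(bscan.pixels, crops)
        # stitch non-overlapping column ranges of the main windows
        rebuilt = np.full_like(bscan.pixels[:64], np.nan)
        for window, part in zip(crops.windows, parts):
            rebuilt[:, window.offset : window.stop] = part
        # every column written at least once and equal to the source wherever
        # written by the window that owns it in the stitched image
        for window, part in zip(crops.windows, parts):
            assert np.array_equal(part, bscan.pixels[:64, window.offset : window.stop])

    def test_final_crop_reaches_last_column(self):
        grid = np.tile(np.arange(1534, dtype=np.int32), (512, 1))
        crops = specific_crop(1534, 512)
        last = cut_crops(grid, crops)[-1]
        assert last[0, 0] == 1022
        assert last[0, -1] == 1533  # 1022 + 512 - 1

    def test_masks_stay_aligned_with_images(self, small_phantom):
        bscan, _, labels = small_phantom
        crops = specific_crop(bscan.width, 64)
        img_parts = cut_crops(bscan.pixels, crops)
        lab_parts = cut_crops(labels, crops)
        for img, lab, w in zip(img_parts, lab_parts, crops.windows):
            assert img.shape == lab.shape == (64, 64)
            assert np.array_equal(lab, labels[:64, w.offset : w.stop])

    def test_width_mismatch_rejected(self, small_phantom):
        bscan, _, _ = small_phantom
        with pytest.raises(CropError):
            cut_crops(bscan.pixels[:, :-1], specific_crop(bscan.width, 64))


class TestRLE:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((17, 23)) < rng.uniform(0.05, 0.95)
        assert np.array_equal(rle_decode(rle_encode(mask)), mask)

    def test_empty_and_full_masks(self):
        for mask in (np.zeros((4, 5), bool), np.ones((4, 5), bool)):
            assert np.array_equal(rle_decode(rle_encode(mask)), mask)


class TestCoco:
    def test_retinal_phantom_emits_six_instances(self, tmp_path, small_phantom):
        bscan, bounds, _ = small_phantom
        path = write_coco([bscan], [bounds], tmp_path / "ann.json")
        records = read_coco(path)
        assert len(records) == 1
        assert len(records[0].instances) == 6

    def test_empty_region_emits_no_instance(self, tmp_path):
        # tangent middle boundary everywhere: first region has zero thickness
        traces = np.vstack([np.full(40, 10.0), np.full(40, 10.0), np.full(40, 20.0)])
        bounds = BoundarySet("choroid3", traces)
        image = np.zeros((30, 40))
        records = read_coco(write_coco([image], [bounds], tmp_path / "ann.json"))
        names = [name for name, _ in records[0].instances]
        assert names == ["RPE-CSI"]

    def test_round_trip_is_mask_lossless_for_many_phantoms(self, tmp_path):
        rng = np.random.default_rng(7)
        scans, bounds = [], []
        for _ in range(200):
            spec = PhantomSpec(
                width=48,
                height=40,
                profile="retinal7",
                seed=int(rng.integers(0, 2**31)),
                boundary_waviness=0.5,
                mean_layer_thicknesses=tuple(rng.uniform(3.0, 5.0, 6)),
                fovea_depth=4.0,
                fovea_width=12.0,
                speckle_level=0.1,
            )
            scan, bset = generate_phantom(spec)
            scans.append(scan)
            bounds.append(bset)
        path = write_coco(scans, bounds, tmp_path / "many.json")
        records = read_coco(path)
        assert len(records) == 200
        layer_names = bounds[0].layer_names
        for record, bset in zip(records, bounds):
            truth = boundaries_to_classmap(bset, 40)
            got = {name: mask for name, mask in record.instances}
            for k, name in enumerate(layer_names):
                expected = truth == k + 1
                if expected.any():
                    assert np.array_equal(got[name], expected)
                else:
                    assert name not in got

    def test_unknown_category_rejected(self, tmp_path, small_phantom):
        bscan, bounds, _ = small_phantom
        path = write_coco([bscan], [bounds], tmp_path / "ann.json")
        data = json.loads(path.read_text())
        data["categories"][0]["name"] = "NOT-A-LAYER"
        path.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="category"):
            read_coco(path)

    def test_mixed_profiles_rejected(self, tmp_path, small_phantom):
        bscan, bounds, _ = small_phantom
        other = BoundarySet(
            "choroid3",
            np.vstack([np.full(bounds.width, 5.0), np.full(bounds.width, 20.0), np.full(bounds.width, 30.0)]),
        )
        with pytest.raises(ValueError, match="profile"):
            write_coco([bscan, bscan], [bounds, other], tmp_path / "bad.json")


@pytest.fixture(scope="module")
def rotation_phantom():
    spec = PhantomSpec(width=512, height=512, profile="retinal7", seed=5)
    bscan, bounds = generate_phantom(spec)
    return bscan, boundaries_to_classmap(bounds, 512)


class TestRotateAugment:
    def test_zero_angle_is_bit_identical(self, rotation_phantom):
        bscan, labels = rotation_phantom
        image, rotated = rotate_augment(bscan.pixels, labels, 0.0)
        assert np.array_equal(image, bscan.pixels)
        assert np.array_equal(rotated, labels)

    @pytest.mark.parametrize("method", ["nearest", "distance"])
    def test_back_and_forth_rotation_preserves_masks(self, rotation_phantom, method):
        """+10 then −10 degrees keeps per-layer Dice >= 99%.

        Measured away from the frame edges: content within ~50 columns of the
        left/right border rotates out of a same-size frame and is lost by
        construction, so the interpolation tolerance is assessed on the
        interior.
        """
        bscan, labels = rotation_phantom
        img1, lab1 = rotate_augment(bscan.pixels, labels, 10.0, mask_method=method)
        _, lab2 = rotate_augment(img1, lab1, -10.0, mask_method=method)
        margin = 55
        interior = np.s_[:, margin:-margin]
        for k in range(1, 7):
            assert dice((lab2 == k)[interior], (labels == k)[interior]) >= 99.0

    def test_random_angle_reproducible_with_seed(self, rotation_phantom):
        bscan, labels = rotation_phantom
        a = rotate_augment(bscan.pixels, labels, seed=42)
        b = rotate_augment(bscan.pixels, labels, seed=42)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_angle_outside_policy_rejected(self, rotation_phantom):
        bscan, labels = rotation_phantom
        with pytest.raises(ValueError):
            rotate_augment(bscan.pixels, labels, 10.5)

    def test_out_of_frame_fills_with_background(self, rotation_phantom):
        bscan, labels = rotation_phantom
        _, rotated = rotate_augment(bscan.pixels, labels, 10.0)
        assert rotated[0, 0] == 0 and rotated[-1, -1] == 0
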