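"""Label I/O, augmentation primitives, planning, and splitting."""

import numpy as np
import pytest

from wattdet.dataio import (AugmentationPlan, BoxAnnotation, DatasetItem,
                            brightness, class_counts, execute_plan, hflip,
                            motion_blur, plan_augmentation, read_yolo_labels,
                            stratified_split, write_yolo_labels)
from wattdet.errors import ConfigurationError, ParseError, SchemaError

# printed per-class instance counts of the source data and the augmented
# totals the pipeline is balanced towards
ORIGINAL_COUNTS = {"stand": 3306, "walk": 1015, "side": 2745,
                   "lie": 3080, "eat": 1738, "drink": 1155}
TARGET_COUNTS = {"stand": 7800, "walk": 7500, "side": 7700,
                 "lie": 7900, "eat": 7600, "drink": 7500}


class TestLabelIO:
    def test_single_line_walk_box(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("1 0.5 0.5 0.2 0.3\n")
        (a,) = read_yolo_labels(p)
        assert a.class_name == "walk"
        assert (a.cx, a.cy, a.w, a.h) == (0.5, 0.5, 0.2, 0.3)

    def test_empty_file_background(self, tmp_path):
        p = tmp_path / "bg.txt"
        p.write_text("")
        assert read_yolo_labels(p) == []

    def test_roundtrip_100_random_boxes(self, tmp_path, rng):
        annots = []
        for _ in range(100):
            w, h = rng.uniform(0.05, 0.3, 2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            annots.append(BoxAnnotation(int(rng.integers(6)),
                                        round(cx, 6), round(cy, 6),
                                        round(w, 6), round(h, 6)))
        p = tmp_path / "r.txt"
        write_yolo_labels(annots, p)
        back = read_yolo_labels(p)
        for a, b in zip(annots, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert getattr(a, f) == pytest.approx(getattr(b, f),
                                                      abs=1e-6)

    def test_bad_class_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("9 0.5 0.5 0.2 0.2\n")
        with pytest.raises(SchemaError):
            read_yolo_labels(p)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\n1 0.5 oops 0.2\n")
        with pytest.raises(ParseError) as e:
            read_yolo_labels(p)
        assert e.value.line_no == 2

    def test_conflicting_duplicate_rejected(self, tmp_path):
        p = tmp_path / "dup.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\n3 0.5 0.5 0.2 0.2\n")
        with pytest.raises(SchemaError):
            read_yolo_labels(p)

    def test_boxes_clipped_into_unit_square(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("0 0.02 0.5 0.1 0.2\n")
        (a,) = read_yolo_labels(p)
        assert a.cx - a.w / 2 >= 0.0


class TestBoxAnnotation:
    def test_invalid_class(self):
        with pytest.raises(SchemaError):
            BoxAnnotation(6, 0.5, 0.5, 0.1, 0.1)

    def test_nonpositive_size(self):
        with pytest.raises(SchemaError):
            BoxAnnotation(0, 0.5, 0.5, 0.0, 0.1)


class TestHflip:
    def test_cx_mirrored(self, rng):
        img = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        _, (a,) = hflip(img, [BoxAnnotation(0, 0.3, 0.4, 0.2, 0.2)])
        assert a.cx == pytest.approx(0.7)
        assert (a.cy, a.w, a.h) == (0.4, 0.2, 0.2)

    def test_involution(self, rng):
        img = rng.integers(0, 255, (6, 10, 3), dtype=np.uint8)
        annots = [BoxAnnotation(2, 0.25, 0.5, 0.3, 0.4)]
        img2, an2 = hflip(*hflip(img, annots))
        assert np.array_equal(img, img2)
        assert an2[0] == annots[0]

    def test_center_fixed_point(self, rng):
        img = rng.integers(0, 255, (4, 4), dtype=np.uint8)
        _, (a,) = hflip(img, [BoxAnnotation(0, 0.5, 0.5, 0.2, 0.2)])
        assert a.cx == 0.5


class TestIntensityOps:
    def test_brightness_identity(self, rng):
        img = rng.integers(0, 255, (5, 5, 3), dtype=np.uint8)
        assert np.array_equal(brightness(img, 1.0), img)

    def test_brightness_clips(self):
        img = np.full((4, 4, 3), 128, dtype=np.uint8)
        out = brightness(img, 2.0)
        assert out.max() == 255

    def test_motion_blur_constant_unchanged(self):
        img = np.full((9, 9, 3), 77, dtype=np.uint8)
        out = motion_blur(img, kernel_len=7, angle=30.0)
        assert np.array_equal(out, img)

    def test_motion_blur_kernel_mean_preserving(self, rng):
        img = rng.integers(0, 255, (16, 16), dtype=np.uint8)
        out = motion_blur(img, 5, 0.0)
        # interior mean approximately preserved by a normalized kernel
        assert abs(float(out[4:-4, 4:-4].mean())
                   - float(img[2:-2, 2:-2].mean())) < 12


class TestPlanAugmentation:
    def test_walk_deficit_from_printed_counts(self):
        plan = plan_augmentation(ORIGINAL_COUNTS, TARGET_COUNTS)
        assert plan.deficits["walk"] == 7500 - 1015 == 6485

    def test_all_printed_deficits_nonnegative(self):
        plan = plan_augmentation(ORIGINAL_COUNTS, TARGET_COUNTS)
        assert all(d >= 0 for d in plan.deficits.values())
        expected = {"stand": 4494, "walk": 6485, "side": 4955,
                    "lie": 4820, "eat": 5862, "drink": 6345}
        assert plan.deficits == expected

    def test_no_deficit_empty_plan(self):
        plan = plan_augmentation({"walk": 10}, {"walk": 10})
        assert plan.empty

    def test_target_below_current_rejected(self):
        with pytest.raises(ConfigurationError):
            plan_augmentation({"walk": 10}, {"walk": 5})

    def test_motion_blur_reserved_for_walk_by_default(self):
        plan = plan_augmentation(ORIGINAL_COUNTS, TARGET_COUNTS)
        for name, ops in plan.ops.items():
            assert ("motion_blur" in ops) == (name == "walk")


def _tiny_items(rng, n=6):
    items = []
    for i in range(n):
        img = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        annots = [BoxAnnotation(i % 6, 0.5, 0.5, 0.4, 0.4)]
        items.append(DatasetItem(img, annots, name=f"im{i}"))
    return items


class TestExecutePlan:
    def test_counts_reach_targets(self, rng):
        items = _tiny_items(rng, 12)
        current = {n: int(c) for n, c in
                   zip(("stand", "walk", "side", "lie", "eat", "drink"),
                       class_counts(items))}
        targets = {"walk": current["walk"] + 5, "eat": current["eat"] + 3}
        plan = plan_augmentation(current, targets)
        out = execute_plan(items, plan, seed=4)
        final = class_counts(out)
        assert final[1] >= targets["walk"]
        assert final[4] >= targets["eat"]

    def test_deterministic_under_seed(self, rng):
        items = _tiny_items(rng, 12)
        plan = plan_augmentation({"walk": 2}, {"walk": 6})
        a = execute_plan(items, plan, seed=9)
        b = execute_plan(items, plan, seed=9)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert x.annots == y.annots

    def test_annotations_stay_valid(self, rng):
        items = _tiny_items(rng, 12)
        plan = plan_augmentation({"walk": 2}, {"walk": 8})
        for it in execute_plan(items, plan, seed=2):
            for a in it.annots:
                assert 0 <= a.cx - a.w / 2 and a.cx + a.w / 2 <= 1
                assert 0 <= a.cy - a.h / 2 and a.cy + a.h / 2 <= 1


class TestStratifiedSplit:
    def test_ten_groups_eight_two(self, rng):
        items = [DatasetItem(None, [BoxAnnotation(0, .5, .5, .2, .2)],
                             group=f"g{i}") for i in range(10)]
        train, val = stratified_split(items, 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2

    def test_same_seed_identical(self, rng):
        items = _tiny_items(rng, 20)
        a = stratified_split(items, 0.8, seed=5)
        b = stratified_split(items, 0.8, seed=5)
        assert [it.name for it in a[0]] == [it.name for it in b[0]]

    def test_groups_never_straddle(self, rng):
        items = []
        for i in range(30):
            items.append(DatasetItem(
                None, [BoxAnnotation(i % 6, .5, .5, .2, .2)],
                group=f"vid{i % 7}", name=f"f{i}"))
        train, val = stratified_split(items, 0.7, seed=3)
        tg = {it.group for it in train}
        vg = {it.group for it in val}
        assert not tg & vg

    def test_class_proportions_near_ratio(self, rng):
        items = []
        for i in range(400):
            cls = int(rng.integers(6))
            items.append(DatasetItem(None,
                                     [BoxAnnotation(cls, .5, .5, .2, .2)],
                                     name=f"i{i}"))
        train, val = stratified_split(items, 0.8, seed=1)
        total = class_counts(items)
        tr = class_counts(train)
        frac = tr / np.maximum(total, 1)
        assert np.all(np.abs(frac - 0.8) < 0.05)

    def test_bad_ratio(self):
        with pytest.raises(ConfigurationError):
            stratified_split([], ratio=1.5)


def test_augmentation_plan_schema():
    with pytest.raises(SchemaError):
        AugmentationPlan({"walk": 1}, {"fly": 2})
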