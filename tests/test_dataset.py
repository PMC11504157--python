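"""Polygon rasterization, data splitting, and augmentation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tkvnet.dataset import (AnnotationError, AugmentationParams, LabeledPair,
                            PolygonAnnotation, augment_pair, polygons_to_mask,
                            read_labelme, split_by_patient, split_train_val,
                            write_labelme)


def _poly(vertices, label="left_kidney"):
    return PolygonAnnotation(label, tuple(vertices))


def _point_in_polygon_oracle(x, y, verts, tol=1e-12):
    """Brute-force even-odd ray casting with an explicit on-boundary check."""
    n = len(verts)
    # boundary
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < tol * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
            if min(x1, x2) - tol <= x <= max(x1, x2) + tol and \
                    min(y1, y2) - tol <= y <= max(y1, y2) + tol:
                return True
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestPolygonsToMask:
    def test_empty_annotations_give_zero_mask(self):
        assert polygons_to_mask([], (16, 16)).sum() == 0

    def test_integer_rectangle_counts_inclusive_centres(self):
        rect = _poly([(10, 10), (19, 10), (19, 19), (10, 19)])
        assert polygons_to_mask([rect], (64, 64)).sum() == 100

    def test_random_triangles_match_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            verts = [tuple(rng.uniform(0.3, 30.7, 2)) for _ in range(3)]
            # skip nearly degenerate triangles where boundary rules may differ
            area = abs(
                (verts[1][0] - verts[0][0]) * (verts[2][1] - verts[0][1])
                - (verts[2][0] - verts[0][0]) * (verts[1][1] - verts[0][1])) / 2
            if area < 1.0:
                continue
            mask = polygons_to_mask([_poly(verts)], (32, 32))
            oracle = np.zeros((32, 32), dtype=np.uint8)
            for r in range(32):
                for c in range(32):
                    oracle[r, c] = _point_in_polygon_oracle(c, r, verts)
            np.testing.assert_array_equal(mask, oracle)

    def test_left_and_right_merge_into_one_foreground(self):
        l = _poly([(2, 2), (8, 2), (8, 8), (2, 8)], "left_kidney")
        r = _poly([(12, 2), (18, 2), (18, 8), (12, 8)], "right_kidney")
        mask = polygons_to_mask([l, r], (24, 24))
        assert mask.sum() == 2 * 49
        assert set(np.unique(mask)) <= {0, 1}

    def test_area_approaches_shoelace_area(self):
        # 100x100-px rectangle: rasterized count within 2% of shoelace area
        rect = _poly([(5.3, 5.7), (105.3, 5.7), (105.3, 105.7), (5.3, 105.7)])
        count = polygons_to_mask([rect], (128, 128)).sum()
        assert abs(count - 100.0 * 100.0) / 1e4 < 0.02

    def test_too_few_vertices_rejected(self):
        with pytest.raises(AnnotationError):
            _poly([(0, 0), (1, 1)])

    def test_bad_label_rejected(self):
        with pytest.raises(AnnotationError):
            _poly([(0, 0), (1, 0), (1, 1)], label="spleen")


class TestLabelmeIO:
    def test_round_trip(self, tmp_path):
        anns = [_poly([(1.5, 2.5), (9.0, 2.0), (5.0, 9.5)], "right_kidney")]
        path = tmp_path / "slice_0000.json"
        write_labelme(path, anns, (64, 48), image_path="slice_0000.dcm")
        back, shape = read_labelme(path)
        assert shape == (64, 48)
        assert back[0].label == "right_kidney"
        assert back[0].vertices == anns[0].vertices
        doc = json.loads(path.read_text())
        assert {"shapes", "imageHeight", "imageWidth"} <= doc.keys()


class TestSplit:
    def test_published_image_counts(self):
        train, val = split_train_val(list(range(1483)), 0.8, seed=42)
        assert (len(train), len(val)) == (1186, 297)

    def test_exact_division(self):
        train, val = split_train_val(list(range(10)), 0.8, seed=0)
        assert (len(train), len(val)) == (8, 2)

    def test_deterministic_partition(self):
        items = list(range(100))
        a = split_train_val(items, 0.8, seed=5)
        b = split_train_val(items, 0.8, seed=5)
        c = split_train_val(items, 0.8, seed=6)
        assert a == b
        assert a != c
        assert sorted(a[0] + a[1]) == items

    @given(n=st.integers(1, 500), frac=st.floats(0.05, 0.95),
           seed=st.integers(0, 2 ** 16))
    @settings(max_examples=50, derandomize=True)
    def test_sizes_sum_and_partition(self, n, frac, seed):
        train, val = split_train_val(list(range(n)), frac, seed)
        assert len(train) == int(np.floor(n * frac))
        assert len(train) + len(val) == n
        assert set(train).isdisjoint(val)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_train_val([], 0.8, 0)

    def test_patient_split_never_leaks_subjects(self):
        items = [(f"subj{i % 5}", k) for i, k in enumerate(range(50))]
        train, val = split_by_patient(items, lambda it: it[0], 0.8, seed=1)
        assert {s for s, _ in train}.isdisjoint({s for s, _ in val})
        assert len(train) + len(val) == 50


class _ScriptedDraw:
    """Stands in for a Generator, returning scripted uniform() values."""

    def __init__(self, values):
        self.values = list(values)

    def uniform(self, lo, hi):
        return self.values.pop(0)

    def random(self):
        return 1.0


def _impulse_pair(r, c, size=33):
    img = np.zeros((size, size))
    img[r, c] = 1.0
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[r, c] = 1
    return LabeledPair(img, mask)


class TestAugmentPair:
    def test_zero_params_are_identity(self):
        rng = np.random.default_rng(0)
        pair = _impulse_pair(10, 20)
        params = AugmentationParams(rotation_max_deg=0, shift_max_frac=0,
                                    zoom_max_frac=0)
        out = augment_pair(pair, params, rng)
        np.testing.assert_array_equal(out.image, pair.image)
        np.testing.assert_array_equal(out.mask, pair.mask)

    def test_pure_90_degree_rotation_moves_impulse_analytically(self):
        # scripted draw: angle=90 deg, shifts 0, zoom 1
        pair = _impulse_pair(6, 24, size=33)
        params = AugmentationParams(rotation_max_deg=90)
        out = augment_pair(pair, params, _ScriptedDraw([90.0, 0.0, 0.0, 1.0]))
        centre = 16.0
        dr, dc = 6 - centre, 24 - centre
        # inverse rotation by 90 deg maps offset (dr, dc) -> (dc, -dr)
        want_r, want_c = centre + dc, centre - dr
        got = np.argwhere(out.mask)
        assert len(got) >= 1
        r, c = got[np.argmin(np.abs(got - [want_r, want_c]).sum(axis=1))]
        assert abs(r - want_r) <= 1 and abs(c - want_c) <= 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_closure_shapes_ranges_binary(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((40, 40))
        mask = (rng.random((40, 40)) > 0.7).astype(np.uint8)
        out = augment_pair(LabeledPair(img, mask), AugmentationParams(), rng)
        assert out.image.shape == (40, 40) and out.mask.shape == (40, 40)
        assert 0.0 <= out.image.min() and out.image.max() <= 1.0
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_shift_moves_content(self):
        pair = _impulse_pair(16, 16)
        params = AugmentationParams(rotation_max_deg=0, zoom_max_frac=0,
                                    shift_max_frac=0.3)
        out = augment_pair(pair, params, _ScriptedDraw([0.0, 5 / 33, 3 / 33, 1.0]))
        assert out.mask[21, 19] == 1
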