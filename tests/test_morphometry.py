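"""Shape metrics against analytic anchors and brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

import isletquant as iq
from isletquant.morphometry import CIRCULARITY_EPS


def disc_mask(radius, pad=10):
    n = 2 * (radius + pad)
    m = np.zeros((n, n), bool)
    rr, cc = draw_disk((n / 2, n / 2), radius, shape=m.shape)
    m[rr, cc] = True
    return m


def random_blob(rng, size=48):
    """Connected random blob: dilated union of a few random discs."""
    m = np.zeros((size, size), bool)
    anchor = (size // 2, size // 2)
    for _ in range(rng.integers(2, 6)):
        r = int(rng.integers(2, 8))
        cy = int(np.clip(anchor[0] + rng.integers(-8, 9), r + 1, size - r - 2))
        cx = int(np.clip(anchor[1] + rng.integers(-8, 9), r + 1, size - r - 2))
        rr, cc = draw_disk((cy, cx), r, shape=m.shape)
        m[rr, cc] = True
    # keep the largest connected component only
    lab, n = ndi.label(m, structure=np.ones((3, 3), int))
    if n > 1:
        sizes = ndi.sum_labels(m, lab, index=range(1, n + 1))
        m = lab == (1 + int(np.argmax(sizes)))
    return m


class TestShapeMetrics:
    def test_ideal_disc_anchor(self):
        """A perfect circle has circularity 1.0; Feret and effective
        diameter both equal its diameter."""
        m = disc_mask(200, pad=56)  # 512x512 raster
        s = iq.shape_metrics(m, pixel_size=1.0)
        assert s.circularity == pytest.approx(1.0, abs=0.02)
        assert s.feret == pytest.approx(400.0, rel=0.01)
        assert s.effective_diameter == pytest.approx(s.feret, rel=0.005)

    def test_bar_circularity_decreases_with_length(self):
        prev = np.inf
        for n in (8, 16, 32, 64, 128):
            m = np.zeros((5, n + 4), bool)
            m[2, 2 : 2 + n] = True
            c = iq.shape_metrics(m).circularity
            assert c < prev
            prev = c

    def test_ellipse_circularity_decreases_with_aspect(self):
        prev = np.inf
        for aspect in (1, 2, 4, 8):
            a = int(60 / np.sqrt(aspect))
            b = int(60 * np.sqrt(aspect))
            n = 2 * b + 20
            m = np.zeros((n, n), bool)
            rr, cc = draw_ellipse(n // 2, n // 2, a, b, shape=m.shape)
            m[rr, cc] = True
            c = iq.shape_metrics(m).circularity
            assert c < prev
            prev = c

    def test_feret_equals_brute_force_on_random_blobs(self):
        """Oracle: O(n^2) scan over all boundary-pixel corner pairs."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = random_blob(rng)
            pts = np.argwhere(m & ~ndi.binary_erosion(m, border_value=0)).astype(float)
            corners = np.concatenate(
                [pts + [dr, dc] for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)]
            )
            brute = 0.0
            for i in range(len(corners)):
                d = np.hypot(*(corners[i + 1 :] - corners[i]).T)
                if len(d):
                    brute = max(brute, float(d.max()))
            assert iq.feret_diameter(m) == pytest.approx(brute, abs=1e-9)

    def test_feret_at_least_effective_diameter(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            s = iq.shape_metrics(random_blob(rng))
            assert s.feret >= s.effective_diameter * (1 - 1e-9)

    def test_single_pixel_conventions(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        s = iq.shape_metrics(m, pixel_size=2.0)
        assert s.perimeter == 8.0
        assert s.feret == pytest.approx(2.0 * np.sqrt(2.0))
        assert s.area == 4.0
        assert s.circularity <= 1.0 + CIRCULARITY_EPS

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        m = random_blob(rng)
        big = np.zeros((96, 96), bool)
        big[5 : 5 + m.shape[0], 7 : 7 + m.shape[1]] = m
        shifted = np.roll(np.roll(big, 17, axis=0), 23, axis=1)
        a = iq.shape_metrics(big)
        b = iq.shape_metrics(shifted)
        for attr in ("area", "perimeter", "circularity", "feret"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-9)

    def test_rotation_90_within_one_percent(self):
        rng = np.random.default_rng(6)
        m = random_blob(rng)
        a = iq.shape_metrics(m)
        b = iq.shape_metrics(np.rot90(m))
        assert a.area == b.area
        assert a.perimeter == pytest.approx(b.perimeter, rel=0.01)
        assert a.feret == pytest.approx(b.feret, rel=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            iq.shape_metrics(np.zeros((4, 4), bool))


class TestSizeClassify:
    def test_singlet_below_two_cell_areas(self):
        assert iq.size_classify(78.0, 10.0) == "singlet"

    def test_boundary_goes_to_larger_class(self):
        d_at = 30.0
        assert iq.size_classify(1000.0, 29.9) == "small_cluster"
        assert iq.size_classify(1000.0, d_at) == "islet"


class TestDetectObjects:
    def test_closing_merges_nearby_discs(self):
        """Two 5-um discs 5 um apart: one object at merge radius 10,
        two at merge radius 0."""
        masks = {t: np.zeros((64, 64), bool) for t in iq.CELL_TYPES}
        for cx in (20, 35):  # gap = 35-20-2*5 = 5 um
            rr, cc = draw_disk((32, cx), 5)
            masks["beta"][rr, cc] = True
        ms = iq.MaskSet(
            masks=masks,
            tissue_mask=np.ones((64, 64), bool),
            threshold_record={},
            pixel_size=1.0,
        )
        assert len(iq.detect_objects(ms, merge_radius=10.0)) == 1
        assert len(iq.detect_objects(ms, merge_radius=0.0)) == 2

    def test_empty_masks_give_empty_list(self):
        ms = iq.MaskSet(
            masks={t: np.zeros((16, 16), bool) for t in iq.CELL_TYPES},
            tissue_mask=np.ones((16, 16), bool),
            threshold_record={},
            pixel_size=1.0,
        )
        assert iq.detect_objects(ms) == []

    def test_negative_merge_radius_rejected(self, rich_masks):
        with pytest.raises(ValueError):
            iq.detect_objects(rich_masks, merge_radius=-1.0)

    def test_zero_radius_equals_flood_fill(self, rich_masks):
        """Oracle: plain 8-connected component labeling of the mask union."""
        objs = iq.detect_objects(rich_masks, merge_radius=0.0)
        _, n = ndi.label(rich_masks.union, structure=np.ones((3, 3), int))
        assert len(objs) == n

    def test_object_count_matches_ground_truth(self, rich_section, rich_objects):
        """Detected objects vs generator truth (sub-min-size excluded)."""
        _, truth = rich_section
        n_truth = int((truth.object_table.area_px >= 25).sum())
        assert abs(len(rich_objects) - n_truth) <= max(1, round(0.05 * n_truth))

    def test_per_type_areas_sum_to_object_area(self, rich_objects):
        for o in rich_objects:
            assert sum(o.per_type_area.values()) == pytest.approx(o.area, abs=1.0)

    def test_composition_sums_to_one(self, rich_objects):
        for o in rich_objects:
            assert sum(o.composition.values()) == pytest.approx(1.0, abs=1e-9)

    def test_objects_sorted_by_decreasing_area(self, rich_objects):
        areas = [o.area for o in rich_objects]
        assert areas == sorted(areas, reverse=True)
        assert [o.object_id for o in rich_objects] == list(range(1, len(rich_objects) + 1))

    def test_pure_pp_cluster_flagged_contains_pp(self, rich_objects):
        pp_objs = [o for o in rich_objects if o.composition["pp"] > 0.99]
        assert pp_objs
        assert all(o.contains_pp for o in pp_objs)

    def test_frame_export_columns(self, rich_objects):
        df = iq.objects_to_frame(rich_objects, block_index=3)
        assert len(df) == len(rich_objects)
        assert (df.block_index == 3).all()
        for t in iq.CELL_TYPES:
            assert f"comp_{t}" in df.columns
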