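import numpy as np
import pytest

from posturekit import (GeometryError, MannequinSpec, MissingKeypointError,
                        SegmentationError, build_trimap, generate,
                        segment_silhouette, subject_box)
from posturekit.silhouette import (CERTAIN_BG, CERTAIN_FG, PROBABLE_BG, Rect,
                                   band_thickness, subject_box)
from posturekit._geometry import point_segment_distance

from conftest import make_keypoints


def _box_kps():
    return make_keypoints(
        {"REar": (400.0, 100.0), "RA": (420.0, 700.0),
         "LSH": (300.0, 200.0), "RSH": (500.0, 200.0)},
        width=1000, height=1000)


class TestSubjectBox:
    def test_keypoint_rule_arithmetic(self):
        # literal keypoint-spread rule: height 600 * 1.3, width 200 * 1.3
        box = subject_box(_box_kps(), margin_frac=0.15, min_width_frac=0.0)
        assert box.height == pytest.approx(600 * 1.3, abs=2)
        assert box.width == pytest.approx(200 * 1.3, abs=2)

    def test_zero_margin_is_tight(self):
        box = subject_box(_box_kps(), margin_frac=0.0, min_width_frac=0.0)
        assert box.y0 == 100 and box.y1 == 701
        assert box.x0 == 300 and box.x1 == 501

    def test_clipped_to_image(self):
        kps = make_keypoints(
            {"REar": (30.0, 5.0), "RA": (30.0, 95.0), "LSH": (5.0, 20.0),
             "RSH": (95.0, 20.0)}, width=100, height=100)
        box = subject_box(kps, margin_frac=0.5, min_width_frac=0.0)
        assert box.x0 >= 0 and box.y0 >= 0
        assert box.x1 <= 100 and box.y1 <= 100

    def test_width_floor_covers_sagittal_back(self):
        """On a sagittal mannequin the box must contain the whole true
        silhouette even though the keypoints hug the body axis."""
        spec = MannequinSpec(view="sagittal", trunk_angle_deg=50.0,
                             keypoint_jitter_sigma=0.0, noise_sigma=0.0)
        _, mask, truth = generate(spec)
        box = subject_box(truth.keypoints)
        ys, xs = np.nonzero(mask)
        assert xs.min() >= box.x0 and xs.max() < box.x1
        assert ys.min() >= box.y0 and ys.max() < box.y1

    def test_missing_ear_and_ankle_rejected(self):
        kps = make_keypoints({"LSH": (0.0, 0.0), "RSH": (10.0, 0.0)})
        with pytest.raises(MissingKeypointError):
            subject_box(kps)


class TestBandThickness:
    def test_scale_of_length(self):
        kps = make_keypoints({"RK": (0.0, 0.0), "RA": (0.0, 100.0)})
        assert band_thickness(kps, ("RK", "RA"), scale=0.15) == pytest.approx(15.0)

    def test_floor_of_two_pixels(self):
        kps = make_keypoints({"RK": (0.0, 0.0), "RA": (0.0, 10.0)})
        assert band_thickness(kps, ("RK", "RA"), scale=0.15) == pytest.approx(2.0)

    def test_zero_length_segment_rejected(self):
        kps = make_keypoints({"RK": (5.0, 5.0), "RA": (5.0, 5.0)})
        with pytest.raises(GeometryError):
            band_thickness(kps, ("RK", "RA"))


class TestBuildTrimap:
    _TINY = {"REar": (4.0, 2.0), "RSH": (4.0, 8.0), "RH": (4.5, 9.0),
             "RK": (5.0, 9.5), "RA": (5.5, 9.8)}

    def _tiny(self):
        return make_keypoints(self._TINY, width=10, height=10)

    def test_small_raster_matches_brute_force_oracle(self):
        kps = self._tiny()
        box = Rect(2, 0, 8, 10)
        tri = build_trimap((10, 10), kps, box, band_thickness_scale=0.15,
                           side="right")
        chain = ("REar", "RSH", "RH", "RK", "RA")
        segs = [(np.array(self._TINY[a]), np.array(self._TINY[b]),
                 band_thickness(kps, (a, b), 0.15))
                for a, b in zip(chain, chain[1:])]
        for i in range(10):
            for j in range(10):
                if not (box.x0 <= j < box.x1 and box.y0 <= i < box.y1):
                    assert tri[i, j] == CERTAIN_BG
                else:
                    in_band = any(
                        point_segment_distance(np.array([j, i], float), a, b) <= tau
                        for a, b, tau in segs)
                    expected = CERTAIN_FG if in_band else PROBABLE_BG
                    assert tri[i, j] == expected, (i, j)

    def test_labels_partition_pixel_count(self):
        spec = MannequinSpec(view="sagittal", trunk_angle_deg=20.0)
        _, _, truth = generate(spec)
        box = subject_box(truth.keypoints)
        tri = build_trimap((640, 480), truth.keypoints, box, side="right")
        counts = [(tri == lbl).sum() for lbl in (CERTAIN_BG, PROBABLE_BG, CERTAIN_FG)]
        assert sum(counts) == 640 * 480
        assert all(c > 0 for c in counts)

    def test_whole_image_box_has_no_certain_bg(self):
        kps = self._tiny()
        tri = build_trimap((10, 10), kps, Rect(0, 0, 10, 10), side="right")
        assert (tri == CERTAIN_BG).sum() == 0

    def test_certain_fg_inside_box(self):
        spec = MannequinSpec(view="frontal", trunk_angle_deg=10.0)
        _, _, truth = generate(spec)
        box = subject_box(truth.keypoints)
        tri = build_trimap((640, 480), truth.keypoints, box)
        ys, xs = np.nonzero(tri == CERTAIN_FG)
        assert xs.min() >= box.x0 and xs.max() < box.x1
        assert ys.min() >= box.y0 and ys.max() < box.y1

    def test_missing_band_keypoints_rejected(self):
        kps = make_keypoints({"REar": (4.0, 2.0), "RSH": (4.0, 8.0)},
                             width=10, height=10)
        with pytest.raises(MissingKeypointError):
            build_trimap((10, 10), kps, Rect(0, 0, 10, 10), side="right")

    def test_bands_inside_true_silhouette(self):
        """Keypoint-seeded foreground must lie inside the true body."""
        for view in ("frontal", "sagittal"):
            spec = MannequinSpec(view=view, trunk_angle_deg=30.0,
                                 keypoint_jitter_sigma=0.0, noise_sigma=0.0)
            _, mask, truth = generate(spec)
            box = subject_box(truth.keypoints)
            tri = build_trimap(mask.shape, truth.keypoints, box,
                               side="right" if view == "sagittal" else None)
            fg = tri == CERTAIN_FG
            assert (fg & ~mask).sum() == 0, view


class TestSegmentSilhouette:
    def test_high_contrast_iou_and_hard_constraints(self, clean_sagittal):
        image, true_mask, truth = clean_sagittal
        box = subject_box(truth.keypoints)
        tri = build_trimap(true_mask.shape, truth.keypoints, box, side="right")
        mask = segment_silhouette(image, tri)
        iou = (mask & true_mask).sum() / (mask | true_mask).sum()
        assert iou >= 0.95
        assert ((tri == CERTAIN_FG) & ~mask).sum() == 0
        assert (mask & (tri == CERTAIN_BG)).sum() == 0

    def test_seedless_trimap_rejected(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        tri = np.full((10, 10), PROBABLE_BG, dtype=np.uint8)
        tri[0] = CERTAIN_BG
        with pytest.raises(SegmentationError):
            segment_silhouette(img, tri)
        tri[:] = CERTAIN_FG
        with pytest.raises(SegmentationError):
            segment_silhouette(img, tri)

    def test_disjoint_blob_not_touching_seeds_dropped(self):
        rng = np.random.default_rng(0)
        img = np.full((60, 60, 3), 230, dtype=np.uint8)
        img[10:30, 10:25] = 40   # subject blob (seeded)
        img[40:55, 40:55] = 40   # stray blob, same colour, unseeded
        tri = np.full((60, 60), CERTAIN_BG, dtype=np.uint8)
        tri[5:58, 5:58] = PROBABLE_BG
        tri[15:25, 15:20] = CERTAIN_FG
        mask = segment_silhouette(img, tri, rng=rng)
        assert mask[20, 17]
        assert not mask[47:52, 47:52].any()

    def test_monotone_contrast_iou(self):
        """IoU does not improve as subject/background contrast shrinks."""
        ious = []
        for offset in (90, 40, 12):
            bg = tuple(min(92 + offset, 255) for _ in range(3))
            spec = MannequinSpec(view="sagittal", trunk_angle_deg=30.0,
                                 keypoint_jitter_sigma=0.0, noise_sigma=5.0,
                                 background_rgb=bg, seed=11,
                                 image_size=(360, 480))
            image, true_mask, truth = generate(spec)
            box = subject_box(truth.keypoints)
            tri = build_trimap(true_mask.shape, truth.keypoints, box, side="right")
            mask = segment_silhouette(image, tri)
            ious.append((mask & true_mask).sum() / (mask | true_mask).sum())
        assert ious[0] >= ious[1] - 0.02
        assert ious[1] >= ious[2] - 0.02
        assert ious[0] >= 0.95
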