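import numpy as np
import pytest

from posturekit import (LandmarkError, MannequinSpec, MissingKeypointError,
                        augment_sagittal, fc_search, generate)
from posturekit.keypoints import Keypoint2D
from posturekit.sagittal import (boundary_pixels, c7_sagittal,
                                 detect_side_and_posterior, l5_sagittal,
                                 ma_sagittal, point_A)

from conftest import make_keypoints, random_blob_mask


def K(x, y):
    return Keypoint2D(float(x), float(y))


def _side_kps(side="right", nose_x=100.0, ear_x=120.0):
    prefix = "R" if side == "right" else "L"
    pts = {
        "N": (nose_x, 50.0),
        f"{prefix}Ear": (ear_x, 55.0), f"{prefix}SH": (118.0, 120.0),
        f"{prefix}H": (115.0, 300.0), f"{prefix}K": (115.0, 420.0),
        f"{prefix}A": (115.0, 540.0),
    }
    return make_keypoints(pts, view="sagittal", width=400, height=600)


class TestSideAndPosterior:
    def test_right_facing_posterior_is_plus_x(self):
        side, post = detect_side_and_posterior(_side_kps(nose_x=100, ear_x=120))
        assert side == "right"
        assert tuple(post) == (1.0, 0.0)

    def test_mirrored_subject_flips_direction(self):
        side, post = detect_side_and_posterior(_side_kps(nose_x=140, ear_x=120))
        assert tuple(post) == (-1.0, 0.0)

    def test_left_side_substituted_when_right_missing(self):
        side, post = detect_side_and_posterior(_side_kps(side="left"))
        assert side == "left"

    def test_no_complete_side_rejected(self):
        kps = make_keypoints({"N": (10.0, 10.0), "RSH": (20.0, 30.0)},
                             view="sagittal")
        with pytest.raises(MissingKeypointError):
            detect_side_and_posterior(kps)


class TestPointA:
    def test_forty_percent_from_shoulder(self):
        kps = make_keypoints({"RSH": (0.0, 10.0), "REar": (0.0, 0.0)})
        a = point_A(kps, K2=40.0)
        assert (a.x, a.y) == pytest.approx((0.0, 6.0))  # 40% toward the ear

    def test_endpoints(self):
        kps = make_keypoints({"RSH": (2.0, 8.0), "REar": (6.0, 0.0)})
        assert (point_A(kps, K2=1e-9 + 0.001).x) == pytest.approx(2.0, abs=1e-3)
        a = point_A(kps, K2=40.0)
        assert (a.x, a.y) == pytest.approx((3.6, 4.8))

    def test_coincident_ear_shoulder_rejected(self):
        from posturekit import GeometryError

        kps = make_keypoints({"RSH": (2.0, 8.0), "REar": (2.0, 8.0)})
        with pytest.raises(GeometryError):
            point_A(kps, K2=40.0)


class TestBoundaryMarches:
    def _rect_mask(self):
        mask = np.zeros((100, 40), dtype=bool)
        mask[:, 10:21] = True  # columns 10..20 inclusive
        return mask

    def test_c7_on_rectangle_edge_both_directions(self):
        mask = self._rect_mask()
        kps = make_keypoints({"RSH": (15.0, 60.0), "REar": (15.0, 40.0)},
                             width=40, height=100)
        a = K(15.0, 50.0)
        c7 = c7_sagittal(mask, kps, a, np.array([1.0, 0.0]))
        assert c7.x == pytest.approx(20.0, abs=0.5) and c7.y == pytest.approx(50.0)
        c7 = c7_sagittal(mask, kps, a, np.array([-1.0, 0.0]))
        assert c7.x == pytest.approx(10.0, abs=0.5)

    def test_march_start_outside_mask_rejected(self):
        mask = self._rect_mask()
        kps = make_keypoints({"RSH": (35.0, 60.0), "REar": (35.0, 40.0)},
                             width=40, height=100)
        with pytest.raises(LandmarkError):
            c7_sagittal(mask, kps, K(35.0, 50.0), np.array([1.0, 0.0]))

    def test_march_exiting_image_inside_mask_rejected(self):
        mask = np.ones((50, 50), dtype=bool)
        kps = make_keypoints({"RSH": (25.0, 40.0), "REar": (25.0, 10.0)},
                             width=50, height=50)
        with pytest.raises(LandmarkError):
            c7_sagittal(mask, kps, K(25.0, 25.0), np.array([1.0, 0.0]))

    def test_l5_march_and_zero_length_case(self):
        mask = self._rect_mask()
        kps = make_keypoints(
            {"RH": (15.0, 90.0), "RK": (15.0, 40.0)}, width=40, height=100)
        l5, l5p = l5_sagittal(mask, kps, K1=20.0,
                              posterior_dir=np.array([1.0, 0.0]))
        assert (l5p.x, l5p.y) == pytest.approx((15.0, 80.0))
        assert l5.x == pytest.approx(20.0, abs=0.5) and l5.y == pytest.approx(80.0)
        # start already at the boundary column: zero-length march
        kps2 = make_keypoints(
            {"RH": (20.0, 90.0), "RK": (20.0, 40.0)}, width=40, height=100)
        l5b, _ = l5_sagittal(mask, kps2, K1=20.0,
                             posterior_dir=np.array([1.0, 0.0]))
        assert l5b.x == pytest.approx(20.0, abs=0.5)

    def test_landmarks_lie_on_mask_boundary(self, clean_sagittal):
        """Each silhouette landmark is in-mask and one pixel further
        along its search direction is out-of-mask."""
        image, mask, truth = clean_sagittal
        lm = augment_sagittal(mask, truth.keypoints)
        post = lm.posterior_dir
        for kp in (lm.C7, lm.L5):
            j, i = int(round(kp.x)), int(round(kp.y))
            assert mask[i, j]
            j2 = int(round(kp.x + 2 * post[0]))
            assert not mask[i, j2]
        j, i = int(round(lm.FC.x)), int(round(lm.FC.y))
        assert mask[i, j]


class TestFCSearch:
    def test_l_shaped_vertex(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:41, 5:11] = True     # vertical bar at the line
        mask[35:41, 5:31] = True     # horizontal foot out to x=30
        c7, l5 = K(10, 10), K(10, 40)
        fc, dist = fc_search(mask, c7, l5, np.array([1.0, 0.0]))
        # vertex pixel (30, 35) by the smaller-y tie-break, localised to
        # the sub-pixel contour (within one pixel of the centre)
        assert fc.y == pytest.approx(35.0)
        assert fc.x == pytest.approx(30.0, abs=1.0)
        assert dist == pytest.approx(20.0, abs=1.0)

    def test_vertical_band_distance(self):
        mask = np.zeros((50, 40), dtype=bool)
        mask[5:45, 10:20] = True  # width 10: columns 10..19
        fc, dist = fc_search(mask, K(10, 10), K(10, 40), np.array([1.0, 0.0]))
        assert dist == pytest.approx(9.0, abs=1.0)

    def test_no_posterior_boundary_rejected(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:15] = True
        with pytest.raises(LandmarkError):
            fc_search(mask, K(14, 5), K(14, 24), np.array([1.0, 0.0]))

    def test_matches_exhaustive_oracle_on_random_blobs(self):
        """fc_search equals a per-pixel brute-force maximum over every
        boundary pixel, with the documented tie-break, on 100 blobs."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(100):
            mask = random_blob_mask(rng)
            ys, xs = np.nonzero(mask)
            c7 = K(xs.min() + 1, ys.min() + 1)
            l5 = K(xs.min() + 2, ys.max() - 1)
            post = np.array([1.0, 0.0])
            # oracle: explicit loop, |ax+by+c|/sqrt(a^2+b^2) per pixel
            a = l5.y - c7.y
            b = c7.x - l5.x
            c = l5.x * c7.y - c7.x * l5.y
            norm = np.hypot(a, b)
            sign = 1.0 if (a * (c7.x + 1) + b * c7.y + c) > 0 else -1.0
            best = None
            for x, y in boundary_pixels(mask):
                d = sign * (a * x + b * y + c) / norm
                if d <= 1e-9:
                    continue
                key = (-d, y, x)
                if best is None or key < best[0]:
                    best = (key, (x, y), d)
            if best is None:
                continue
            fc, dist = fc_search(mask, c7, l5, post)
            assert np.hypot(fc.x - best[1][0], fc.y - best[1][1]) <= 1.0
            assert dist == pytest.approx(best[2], abs=1.0)
            checked += 1
        assert checked >= 90

    def test_ray_variant_agrees_near_boundary_method(self, clean_sagittal):
        image, mask, truth = clean_sagittal
        lm = augment_sagittal(mask, truth.keypoints)
        fc_ray, d_ray = fc_search(mask, lm.C7, lm.L5, lm.posterior_dir,
                                  method="ray")
        assert abs(d_ray - lm.fc_distance) <= 2.0
        assert np.hypot(fc_ray.x - lm.FC.x, fc_ray.y - lm.FC.y) <= 3.0


class TestMASagittal:
    def test_returns_side_ankle_unchanged(self):
        kps = make_keypoints({"RA": (220.0, 900.0), "LA": (210.0, 895.0)})
        assert ma_sagittal(kps, "right").x == 220.0
        assert ma_sagittal(kps, "left").x == 210.0

    def test_missing_ankle_rejected(self):
        kps = make_keypoints({"RSH": (0.0, 0.0)})
        with pytest.raises(MissingKeypointError):
            ma_sagittal(kps, "right")


class TestFullSagittalRecovery:
    @pytest.mark.parametrize("angle", [10.0, 40.0, 70.0])
    def test_recovers_generator_flexion_within_3_degrees(self, angle):
        spec = MannequinSpec(view="sagittal", trunk_angle_deg=angle,
                             keypoint_jitter_sigma=0.0, noise_sigma=0.0,
                             seed=5)
        _, mask, truth = generate(spec)
        lm = augment_sagittal(mask, truth.keypoints)
        from posturekit import measure_tcc

        assert measure_tcc(lm) == pytest.approx(truth.true_angles["tcc"], abs=3.0)

    def test_mirrored_mannequin_measures_identically(self):
        """A left-facing subject (mirrored image) gives the same angles."""
        spec = MannequinSpec(view="sagittal", trunk_angle_deg=35.0,
                             keypoint_jitter_sigma=0.0, noise_sigma=0.0)
        _, mask, truth = generate(spec)
        lm = augment_sagittal(mask, truth.keypoints)
        # mirror the mask and keypoints left-right
        W = spec.image_size[0]
        mask_m = mask[:, ::-1]
        pts = {}
        for name in ("N", "REye", "REar", "NECK", "RSH", "P", "RH", "RK", "RA"):
            kp = truth.keypoints[name]
            mirrored = (W - 1 - kp.x, kp.y)
            target = name.replace("R", "L", 1) if name[0] == "R" and name != "RSH" else name
            pts[name if name in ("N", "NECK", "P") else
                {"REye": "LEye", "REar": "LEar", "RSH": "LSH",
                 "RH": "LH", "RK": "LK", "RA": "LA"}[name]] = mirrored
        kps_m = make_keypoints(pts, view="sagittal", width=W,
                               height=spec.image_size[1])
        lm_m = augment_sagittal(mask_m, kps_m)
        from posturekit import measure_lcc, measure_tcc

        assert measure_tcc(lm_m) == pytest.approx(measure_tcc(lm), abs=1.0)
        assert measure_lcc(lm_m) == pytest.approx(measure_lcc(lm), abs=1.0)
        assert lm_m.side == "left"
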