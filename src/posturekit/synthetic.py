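"""Synthetic mannequin fixtures with closed-form ground truth.

Generates what the measurement pipeline consumes -- a rendered
photograph-like image, the true silhouette mask, a 25-keypoint pose
file -- together with the true landmarks and true angles, so every
pipeline stage is testable without clinical photographs.

The mannequin is a capsule-and-polygon body, not an anatomical mesh:
the pipeline only ever consumes contours and keypoints, so the simplest
geometry with closed-form landmark truth is used. Key constructions:

* Sagittal: the posterior (back) contour is an exact polyline -- a
  straight lumbar edge, a bend vertex at the flexion fulcrum, and a
  straight thoracic+neck edge collinear all the way up. The true C7,
  L5 and FC all lie on this polyline, so the true thoracic flexion
  angle equals the requested bend *exactly*, and the silhouette
  searches of the sagittal augmentation recover the same points up to
  rasterisation.
* Frontal: the upper body leans rigidly about L5; shoulders and ears
  are placed symmetrically about the trunk axis so the shoulder-ear
  diagonal intersection falls exactly on the axis, making the true
  Pisa angle equal the requested lean exactly.

Every band the trimap will draw between adjacent joints is covered by a
slightly larger body capsule, so keypoint-seeded foregrounds are always
inside the true silhouette (up to keypoint jitter).

Randomness (keypoint jitter, pixel noise, battery sampling) is fully
seeded; a fixed seed reproduces fixtures bit-for-bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import angles as angles_mod
from ._geometry import line_ray_intersection, point_segment_distance, unit
from .errors import FormatError
from .keypoints import (BODY25_NAMES, Keypoint2D, MISSING, PoseKeypoints,
                        write_pose_json)

# body proportions, in units of stature
PROPORTIONS = {
    "shank": 0.25,         # ankle -> knee
    "thigh": 0.25,         # knee -> hip
    "trunk": 0.32,         # hip -> shoulder level
    "ear_shoulder": 0.12,  # shoulder -> ear along the neck axis
    "head_radius": 0.085,
    "neck_halfwidth": 0.075,
    "leg_radius": 0.05,
    "l5_rise": 0.05,       # hip -> L5 (K1% of leg length with K1=20)
    "shoulder_halfspan": 0.11,   # frontal
    "ear_halfspan": 0.045,       # frontal
}

BAND_SCALE = 0.15  # must match the trimap default so body covers bands
LEG_OFFSET_FRAC = 0.09  # leg axis depth behind-to-front of the back contour


@dataclass
class MannequinSpec:
    """Parameters of one synthetic fixture."""

    view: str = "sagittal"
    trunk_angle_deg: float = 0.0           # lean (frontal) / flexion (sagittal)
    fulcrum_height_frac: float = 0.5       # sagittal bend position along trunk
    image_size: Tuple[int, int] = (480, 640)   # (width, height)
    subject_height_frac: float = 0.85      # stature / image height
    trunk_halfwidth_frac: float = 0.09     # of stature; BMI proxy
    subject_rgb: Tuple[int, int, int] = (92, 74, 66)
    background_rgb: Tuple[int, int, int] = (203, 203, 208)
    noise_sigma: float = 4.0               # channel units
    lighting_gradient: float = 0.0         # relative left-right brightness ramp
    keypoint_jitter_sigma: float = 2.0     # px, emulates pose-estimator noise
    seed: int = 0

    def __post_init__(self):
        if self.view not in ("frontal", "sagittal"):
            raise FormatError(f"unknown view {self.view!r}")
        if not (0.0 <= self.trunk_angle_deg <= 80.0):
            raise FormatError("trunk_angle_deg must lie in [0, 80]")
        if not (0.0 < self.fulcrum_height_frac < 1.0):
            raise FormatError("fulcrum_height_frac must lie in (0, 1)")
        for c in (*self.subject_rgb, *self.background_rgb):
            if not (0 <= c <= 255):
                raise FormatError("colours must lie in [0, 255]")
        if self.subject_height_frac <= 0.2 or self.subject_height_frac > 1.0:
            raise FormatError("subject_height_frac must lie in (0.2, 1]")

    @property
    def stature_px(self) -> float:
        return self.subject_height_frac * self.image_size[1]

    @property
    def bmi_proxy(self) -> float:
        """Pseudo-BMI mapped linearly from the trunk half-width."""
        return 25.07 + (self.trunk_halfwidth_frac - 0.09) * 150.0


@dataclass
class MannequinTruth:
    """Ground truth of one fixture: keypoints, landmarks, angles, mask."""

    spec: MannequinSpec
    keypoints: PoseKeypoints            # jittered, as a pose estimator would give
    keypoints_clean: PoseKeypoints
    landmarks: Dict[str, Keypoint2D]    # true C7/L5/MA (+FC, A, MH)
    true_angles: Dict[str, float]       # ps or lcc/tcc, degrees
    mask: Optional[np.ndarray] = None   # filled by render()
    _shapes: list = field(default_factory=list, repr=False)


def _kp(p) -> Keypoint2D:
    return Keypoint2D(float(p[0]), float(p[1]), 0.9)


def _capsule(a, b, r):
    return ("capsule", np.asarray(a, float), np.asarray(b, float), float(r))


def _disc(c, r):
    return ("capsule", np.asarray(c, float), np.asarray(c, float), float(r))


def _polygon(vertices):
    return ("polygon", np.asarray(vertices, float))


def _cover_radius(a, b, jitter_sigma) -> float:
    """Radius a body capsule needs so the trimap band over segment a-b
    (thickness BAND_SCALE * length) stays inside the body despite
    keypoint jitter."""
    length = float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))
    return BAND_SCALE * length + 3.0 * jitter_sigma + 3.0


def _build_sagittal(spec: MannequinSpec):
    S = spec.stature_px
    W, H = spec.image_size
    p = PROPORTIONS
    theta = np.radians(spec.trunk_angle_deg)
    jit = spec.keypoint_jitter_sigma

    # random sub-pixel placement phase: photographs are never aligned to
    # the pixel grid, and a shared phase per image size would make the
    # rasterisation error common-mode across a batch
    phase = np.random.default_rng(spec.seed + 2).uniform(0.0, 1.0, size=2)
    x_p = 0.62 * W + phase[0]            # posterior contour line
    r_t = spec.trunk_halfwidth_frac * S
    x_t = x_p - r_t                      # trunk axis
    # legs hang at a fixed offset from the back contour, independent of
    # the trunk width, so body width never moves the true angles
    x_leg = x_p - LEG_OFFSET_FRAC * S
    y_a = 0.92 * H + phase[1]
    y_k = y_a - p["shank"] * S
    y_h = y_k - p["thigh"] * S
    T = p["trunk"] * S

    up = np.array([0.0, -1.0])
    d = np.array([-np.sin(theta), -np.cos(theta)])      # up along upper trunk
    n1 = np.array([np.cos(theta), -np.sin(theta)])      # posterior normal of it
    n0 = np.array([1.0, 0.0])

    B0 = np.array([x_p, y_h + 0.04 * S])                # buttock bottom
    B1 = np.array([x_p, y_h - spec.fulcrum_height_frac * T])  # bend vertex
    B2 = B1 + (1.0 - spec.fulcrum_height_frac) * T * d        # shoulder level
    r_n = p["neck_halfwidth"] * S
    r_h = p["head_radius"] * S
    B3 = B2 + (p["ear_shoulder"] * S + 0.05 * S) * d          # neck top

    SH = B2 - r_n * n1                                   # shoulder keypoint
    HC = SH + p["ear_shoulder"] * S * d - (r_h - r_n) * n1  # head centre = ear
    nose = HC - 0.8 * r_h * n1
    eye = HC + 0.4 * r_h * d - 0.6 * r_h * n1

    hip = np.array([x_leg, y_h])
    knee = np.array([x_leg, y_k])
    ankle = np.array([x_leg, y_a])

    # trunk polygon with a mitred anterior bend
    half = theta / 2.0
    bis = unit(n0 + n1) if np.linalg.norm(n0 + n1) > 1e-9 else n0
    A1 = B1 - 2.0 * r_t * bis / max(np.cos(half), 0.35)
    trunk_poly = _polygon([B0, B1, B2, B2 - 2.0 * r_t * n1, A1,
                           B0 - np.array([2.0 * r_t, 0.0])])
    neck_poly = _polygon([B2, B3, B3 - 2.0 * r_n * n1, B2 - 2.0 * r_n * n1])

    shapes = [
        trunk_poly,
        neck_poly,
        _disc(HC, r_h),
        _capsule(hip, ankle, p["leg_radius"] * S),
        # cover every trimap band with a body capsule
        _capsule(HC, SH, _cover_radius(HC, SH, jit)),
        _capsule(SH, hip, _cover_radius(SH, hip, jit)),
        _capsule(hip, knee, _cover_radius(hip, knee, jit)),
        _capsule(knee, ankle, _cover_radius(knee, ankle, jit)),
    ]

    pts = {
        "N": _kp(nose), "REye": _kp(eye), "REar": _kp(HC),
        "NECK": _kp(SH), "RSH": _kp(SH),
        "P": _kp(hip), "RH": _kp(hip), "RK": _kp(knee), "RA": _kp(ankle),
    }
    clean = PoseKeypoints(dict(pts), view="sagittal",
                          image_width=W, image_height=H)

    # ground-truth landmarks on the posterior polyline
    A_pt = SH + 0.4 * (HC - SH)
    march = unit(_perp_toward(HC - SH, n0))
    C7_t = line_ray_intersection(A_pt, march, B1, B1 + d)
    L5_t = np.array([x_p, y_h - p["l5_rise"] * S])
    FC_t = B1.copy()
    MA_t = ankle.copy()
    landmarks = {
        "C7": _kp(C7_t), "L5": _kp(L5_t), "FC": _kp(FC_t), "MA": _kp(MA_t),
        "A": _kp(A_pt), "L5_prime": _kp(np.array([x_leg, L5_t[1]])),
    }
    true_angles = {
        "tcc": angles_mod.external_angle(FC_t, L5_t, C7_t),
        "lcc": angles_mod.external_angle(L5_t, MA_t, C7_t),
    }
    return clean, landmarks, true_angles, shapes


def _perp_toward(v, hint):
    w = np.array([-v[1], v[0]], dtype=float)
    if float(w @ np.asarray(hint, float)) < 0:
        w = -w
    return w


def _build_frontal(spec: MannequinSpec):
    S = spec.stature_px
    W, H = spec.image_size
    p = PROPORTIONS
    theta = np.radians(spec.trunk_angle_deg)
    jit = spec.keypoint_jitter_sigma

    phase = np.random.default_rng(spec.seed + 2).uniform(0.0, 1.0, size=2)
    x_c = 0.5 * W + phase[0]
    y_a = 0.92 * H + phase[1]
    y_k = y_a - p["shank"] * S
    y_h = y_k - p["thigh"] * S
    leg = p["thigh"] * S

    u = np.array([np.sin(theta), -np.cos(theta)])    # trunk axis, leaning
    u_perp = np.array([np.cos(theta), np.sin(theta)])

    MH = np.array([x_c, y_h])
    L5_t = MH + p["l5_rise"] * S * np.array([0.0, -1.0])
    T_f = 0.35 * S
    C7_t = L5_t + T_f * u
    s_c = L5_t + 0.30 * S * u                         # shoulder centre
    w_sh = p["shoulder_halfspan"] * S
    w_e = p["ear_halfspan"] * S
    # ear line height chosen so the contralateral shoulder-ear diagonals
    # cross exactly at C7_t on the trunk axis
    h_e = (T_f - 0.30 * S) * (w_sh + w_e) / w_sh
    e_c = s_c + h_e * u
    HC = L5_t + (T_f + 0.055 * S) * u

    lsh, rsh = s_c + w_sh * u_perp, s_c - w_sh * u_perp
    lear, rear = e_c + w_e * u_perp, e_c - w_e * u_perp
    lh, rh = MH + 0.07 * S * np.array([1.0, 0.0]), MH - 0.07 * S * np.array([1.0, 0.0])
    lk = np.array([lh[0], y_k])
    rk = np.array([rh[0], y_k])
    la = np.array([x_c + 0.06 * S, y_a])
    ra = np.array([x_c - 0.06 * S, y_a])
    MA_t = np.array([x_c, y_a])

    r_h = p["head_radius"] * S
    shapes = [
        _capsule(MH + 0.03 * S * np.array([0.0, 1.0]), s_c,
                 (spec.trunk_halfwidth_frac + 0.01) * S),
        _disc(HC, r_h),
        _capsule(lsh, rsh, 0.05 * S),
    ]
    for a, b in ((lh, lk), (lk, la), (rh, rk), (rk, ra)):
        shapes.append(_capsule(a, b, max(p["leg_radius"] * S,
                                         _cover_radius(a, b, jit))))
    for a, b in ((lear, lsh), (rear, rsh), (lsh, lh), (rsh, rh)):
        shapes.append(_capsule(a, b, _cover_radius(a, b, jit)))

    pts = {
        "NECK": _kp(s_c), "P": _kp(MH),
        "LSH": _kp(lsh), "RSH": _kp(rsh),
        "LEar": _kp(lear), "REar": _kp(rear),
        "LH": _kp(lh), "RH": _kp(rh),
        "LK": _kp(lk), "RK": _kp(rk),
        "LA": _kp(la), "RA": _kp(ra),
    }
    clean = PoseKeypoints(dict(pts), view="frontal",
                          image_width=W, image_height=H)
    landmarks = {"C7": _kp(C7_t), "L5": _kp(L5_t), "MA": _kp(MA_t), "MH": _kp(MH)}
    true_angles = {"ps": angles_mod.external_angle(L5_t, MA_t, C7_t)}
    return clean, landmarks, true_angles, shapes


def build_skeleton(spec: MannequinSpec) -> MannequinTruth:
    """Keypoints (clean + jittered), true landmarks and true angles."""
    if spec.view == "sagittal":
        clean, landmarks, true_angles, shapes = _build_sagittal(spec)
    else:
        clean, landmarks, true_angles, shapes = _build_frontal(spec)

    rng = np.random.default_rng(spec.seed)
    jittered = {}
    for name in BODY25_NAMES:
        kp = clean[name]
        if kp.missing:
            jittered[name] = MISSING
        elif spec.keypoint_jitter_sigma > 0:
            dx, dy = rng.normal(0.0, spec.keypoint_jitter_sigma, size=2)
            jittered[name] = Keypoint2D(kp.x + dx, kp.y + dy, kp.confidence)
        else:
            jittered[name] = kp
    jit_kps = PoseKeypoints(jittered, view=spec.view,
                            image_width=spec.image_size[0],
                            image_height=spec.image_size[1])
    return MannequinTruth(spec=spec, keypoints=jit_kps, keypoints_clean=clean,
                          landmarks=landmarks, true_angles=true_angles,
                          _shapes=shapes)


def _rasterise(shapes, width: int, height: int) -> np.ndarray:
    from matplotlib.path import Path

    mask = np.zeros((height, width), dtype=bool)
    for shape in shapes:
        if shape[0] == "capsule":
            _, a, b, r = shape
            x0 = max(0, int(np.floor(min(a[0], b[0]) - r - 1)))
            x1 = min(width, int(np.ceil(max(a[0], b[0]) + r + 2)))
            y0 = max(0, int(np.floor(min(a[1], b[1]) - r - 1)))
            y1 = min(height, int(np.ceil(max(a[1], b[1]) + r + 2)))
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            pts = np.stack([xx, yy], axis=-1).astype(float)
            mask[y0:y1, x0:x1] |= point_segment_distance(pts, a, b) <= r
        else:
            _, verts = shape
            x0 = max(0, int(np.floor(verts[:, 0].min() - 1)))
            x1 = min(width, int(np.ceil(verts[:, 0].max() + 2)))
            y0 = max(0, int(np.floor(verts[:, 1].min() - 1)))
            y1 = min(height, int(np.ceil(verts[:, 1].max() + 2)))
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            flat = np.stack([xx.ravel(), yy.ravel()], axis=-1).astype(float)
            inside = Path(verts).contains_points(flat, radius=1e-9)
            mask[y0:y1, x0:x1] |= inside.reshape(yy.shape)
    return mask


def render(spec: MannequinSpec,
           truth: Optional[MannequinTruth] = None) -> Tuple[np.ndarray, np.ndarray, MannequinTruth]:
    """Rasterise the fixture. Returns (image uint8 HxWx3, mask bool, truth)."""
    if truth is None:
        truth = build_skeleton(spec)
    W, H = spec.image_size
    mask = _rasterise(truth._shapes, W, H)
    truth.mask = mask

    img = np.empty((H, W, 3), dtype=np.float64)
    img[...] = np.asarray(spec.background_rgb, dtype=float)
    img[mask] = np.asarray(spec.subject_rgb, dtype=float)
    if spec.lighting_gradient:
        ramp = 1.0 + spec.lighting_gradient * (np.linspace(0, 1, W) - 0.5)
        img *= ramp[None, :, None]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask, truth


def generate(spec: MannequinSpec):
    """Convenience: build + render in one call."""
    truth = build_skeleton(spec)
    image, mask, truth = render(spec, truth)
    return image, mask, truth


@dataclass
class BatteryDesign:
    """Full-factorial fixture design for the robustness analysis.

    Every combination of the listed factor levels is rendered
    ``n_per_cell`` times; trunk half-width (the BMI proxy) and, when
    ``angle_range`` is set, the trunk angle are drawn independently of
    the cell factors -- the null structure the correlation analysis is
    meant to recover.
    """

    views: Sequence[str] = ("sagittal",)
    image_sizes: Sequence[Tuple[int, int]] = ((480, 640),)
    subject_height_fracs: Sequence[float] = (0.85,)
    subject_height_range: Optional[Tuple[float, float]] = None
    background_rgbs: Sequence[Tuple[int, int, int]] = ((203, 203, 208),)
    trunk_angles: Sequence[float] = (30.0,)
    angle_range: Optional[Tuple[float, float]] = None
    fulcrum_height_frac: float = 0.5
    noise_sigma: float = 4.0
    keypoint_jitter_sigma: float = 2.0
    n_per_cell: int = 1
    seed: int = 0

    def cells(self):
        for view in self.views:
            for size in self.image_sizes:
                for shf in self.subject_height_fracs:
                    for bg in self.background_rgbs:
                        for ang in self.trunk_angles:
                            yield view, size, shf, bg, ang


def battery(design: BatteryDesign, out_dir, write_images: bool = True):
    """Render the full factorial design; returns the manifest DataFrame.

    Writes per-fixture PNG image, PNG true mask and pose JSON plus a
    ``manifest.csv`` consumable by the robustness analysis.
    """
    import pandas as pd
    from PIL import Image

    cells = list(design.cells())
    if not cells:
        raise FormatError("battery design has no cells")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    rows = []
    idx = 0
    for view, size, shf, bg, ang in cells:
        for _ in range(design.n_per_cell):
            if design.angle_range is not None:
                ang_i = float(rng.uniform(*design.angle_range))
            else:
                ang_i = float(ang)
            if design.subject_height_range is not None:
                # uncontrolled camera-subject distance: cover factors
                # vary per picture, independent of the posture
                shf_i = float(rng.uniform(*design.subject_height_range))
            else:
                shf_i = shf
            halfwidth = float(rng.uniform(0.075, 0.105))
            spec = MannequinSpec(
                view=view, trunk_angle_deg=ang_i,
                fulcrum_height_frac=design.fulcrum_height_frac,
                image_size=tuple(size), subject_height_frac=shf_i,
                trunk_halfwidth_frac=halfwidth, background_rgb=tuple(bg),
                noise_sigma=design.noise_sigma,
                keypoint_jitter_sigma=design.keypoint_jitter_sigma,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            image, mask, truth = generate(spec)
            stem = f"fix_{idx:04d}"
            img_path = os.path.join(out_dir, f"{stem}.png")
            mask_path = os.path.join(out_dir, f"{stem}_mask.png")
            kp_path = os.path.join(out_dir, f"{stem}_keypoints.json")
            if write_images:
                Image.fromarray(image).save(img_path)
                Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(mask_path)
                write_pose_json(truth.keypoints, kp_path)
            row = {
                "image_path": img_path, "keypoints_path": kp_path,
                "mask_path": mask_path, "view": view,
                "width": size[0], "height": size[1],
                "subject_height_frac": shf_i,
                "background_r": bg[0], "background_g": bg[1], "background_b": bg[2],
                "trunk_angle_deg": ang_i,
                "trunk_halfwidth_frac": halfwidth,
                "bmi": spec.bmi_proxy, "seed": spec.seed,
            }
            for name, val in truth.true_angles.items():
                row[f"true_{name}_deg"] = val
            rows.append(row)
            idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
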