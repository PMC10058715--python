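"""Trimap construction and silhouette extraction.

The subject silhouette is recovered in two steps:

1.  A three-class *trimap* seeded purely from the pose keypoints:
    pixels outside a box around the subject are certain background,
    pixels inside thickened "bands" joining adjacent joints
    (ear-shoulder, shoulder-hip, hip-knee, knee-ankle) are certain
    foreground, and everything else is probable background.
2.  An iterative colour-model graph cut (GrabCut-style) resolves the
    probable-background pixels, respecting the trimap's hard seeds.

The band over joints i, j is the segment between the two keypoints
isotropically expanded by a thickness tau, itself a fraction of the
segment length (bounded so it never exceeds a plausible limb radius).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ._geometry import point_segment_distance
from .errors import GeometryError, MissingKeypointError, SegmentationError
from .keypoints import PoseKeypoints

logger = logging.getLogger(__name__)

# Trimap labels
CERTAIN_BG = 0
PROBABLE_BG = 1
CERTAIN_FG = 2

#: adjacent-joint chains seeding the foreground, per body side
BAND_PAIRS_RIGHT = (("REar", "RSH"), ("RSH", "RH"), ("RH", "RK"), ("RK", "RA"))
BAND_PAIRS_LEFT = (("LEar", "LSH"), ("LSH", "LH"), ("LH", "LK"), ("LK", "LA"))

DEFAULT_BAND_SCALE = 0.15
DEFAULT_BOX_MARGIN = 0.15
DEFAULT_GRAPHCUT_ITERS = 5
MIN_BAND_THICKNESS = 2.0


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in pixel coordinates, [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def slices(self) -> Tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


def _first_present(keypoints: PoseKeypoints, names: Sequence[str]) -> str:
    for n in names:
        if keypoints.has(n):
            return n
    raise MissingKeypointError(list(names))


DEFAULT_MIN_WIDTH_FRAC = 0.45


def _stature_estimate(keypoints: PoseKeypoints, fallback: float) -> float:
    """Bend-invariant body length: the longest complete
    ear-shoulder-hip-knee-ankle chain, else the given fallback."""
    best = 0.0
    for chain in (("REar", "RSH", "RH", "RK", "RA"),
                  ("LEar", "LSH", "LH", "LK", "LA")):
        if keypoints.has(*chain):
            pts = [keypoints[n].xy for n in chain]
            best = max(best, float(sum(
                np.linalg.norm(a - b) for a, b in zip(pts, pts[1:]))))
    return best if best > 0 else fallback


def subject_box(keypoints: PoseKeypoints, margin_frac: float = DEFAULT_BOX_MARGIN,
                image_shape: Optional[Tuple[int, int]] = None,
                min_width_frac: float = DEFAULT_MIN_WIDTH_FRAC) -> Rect:
    """Bounding box around the subject, from the keypoints alone.

    Vertical extent runs from the ear to the ankle (the visible side's,
    falling back to the other), horizontal extent is the tight spread of
    all present keypoints; both are expanded by ``margin_frac`` of their
    extent on every side, then clipped to the image.

    On a perfect sagittal view the keypoints hug the body axis while the
    torso extends a body depth behind them, so the width is floored at
    ``min_width_frac`` of a stature estimate (about the depth a flexed
    standing body can project), centred on the keypoint spread. Stature
    is the ear-shoulder-hip-knee-ankle chain length of a complete side
    (bend-invariant), else the vertical ear-ankle extent. Pass
    ``min_width_frac=0`` for the tight keypoint-only rule.
    """
    ear = keypoints[_first_present(keypoints, ("REar", "LEar"))]
    ankle = keypoints[_first_present(keypoints, ("RA", "LA"))]
    y_lo, y_hi = sorted((ear.y, ankle.y))
    h = y_hi - y_lo
    xy = keypoints.present_xy()
    x_lo, x_hi = float(xy[:, 0].min()), float(xy[:, 0].max())
    w = x_hi - x_lo
    if h <= 0 or w <= 0:
        raise GeometryError("degenerate keypoint spread; cannot form subject box")
    stature = _stature_estimate(keypoints, fallback=h)
    w_eff = max(w, min_width_frac * stature)
    x_c = (x_lo + x_hi) / 2.0
    x0 = x_c - w_eff / 2.0 - margin_frac * w_eff
    x1 = x_c + w_eff / 2.0 + margin_frac * w_eff
    y0 = y_lo - margin_frac * h
    y1 = y_hi + margin_frac * h
    if image_shape is None:
        H = keypoints.image_height or int(np.ceil(y1))
        W = keypoints.image_width or int(np.ceil(x1))
    else:
        H, W = image_shape
    return Rect(
        x0=max(0, int(np.floor(x0))),
        y0=max(0, int(np.floor(y0))),
        x1=min(W, int(np.ceil(x1)) + 1),
        y1=min(H, int(np.ceil(y1)) + 1),
    )


def band_thickness(keypoints: PoseKeypoints, pair: Tuple[str, str],
                   scale: float = DEFAULT_BAND_SCALE) -> float:
    """Band half-thickness tau for the segment joining a keypoint pair.

    tau = scale * |segment|, clamped to [2 px, 0.5 * |segment|] so thin
    detections still seed something and tau never exceeds the radius a
    real limb of that length could have.
    """
    a, b = keypoints.require(*pair)
    length = float(np.linalg.norm(a.xy - b.xy))
    if length <= 0:
        raise GeometryError(f"segment {pair[0]}-{pair[1]} has zero length")
    return max(MIN_BAND_THICKNESS, min(scale * length, 0.5 * length))


def band_pairs_for(keypoints: PoseKeypoints, side: Optional[str] = None):
    """Which joint chains seed the foreground.

    Sagittal views use the visible side only; frontal (posterior) views
    use both sides by symmetry.
    """
    if side == "right":
        return BAND_PAIRS_RIGHT
    if side == "left":
        return BAND_PAIRS_LEFT
    return BAND_PAIRS_RIGHT + BAND_PAIRS_LEFT


def build_trimap(image_shape: Tuple[int, int], keypoints: PoseKeypoints,
                 box: Rect, band_thickness_scale: float = DEFAULT_BAND_SCALE,
                 side: Optional[str] = None) -> np.ndarray:
    """Three-class trimap raster of shape ``image_shape``.

    Outside the box: CERTAIN_BG. Inside any joint band (and the box):
    CERTAIN_FG. Everything else: PROBABLE_BG.
    """
    H, W = image_shape
    pairs = band_pairs_for(keypoints, side)
    missing = [n for pair in pairs for n in pair if not keypoints.has(n)]
    if missing:
        raise MissingKeypointError(sorted(set(missing)))

    trimap = np.full((H, W), CERTAIN_BG, dtype=np.uint8)
    ys, xs = box.slices()
    trimap[ys, xs] = PROBABLE_BG

    if box.width <= 0 or box.height <= 0:
        raise GeometryError("subject box has no area")
    yy, xx = np.mgrid[box.y0:box.y1, box.x0:box.x1]
    pts = np.stack([xx, yy], axis=-1).astype(float)

    fg = np.zeros((box.height, box.width), dtype=bool)
    for pair in pairs:
        tau = band_thickness(keypoints, pair, band_thickness_scale)
        a, b = keypoints.require(*pair)
        fg |= point_segment_distance(pts, a.xy, b.xy) <= tau
    region = trimap[ys, xs]
    region[fg] = CERTAIN_FG
    return trimap


def _postprocess(raw_fg: np.ndarray, trimap: np.ndarray) -> np.ndarray:
    """Keep the component with largest certain-foreground overlap, fill
    holes, and re-impose the hard seeds."""
    labels, n = ndimage.label(raw_fg)
    if n == 0:
        raise SegmentationError("graph cut produced an empty foreground")
    seeds = trimap == CERTAIN_FG
    overlaps = ndimage.sum_labels(seeds, labels, index=np.arange(1, n + 1))
    if overlaps.max() == 0:  # cut detached from seeds; fall back to size
        overlaps = ndimage.sum_labels(raw_fg, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(overlaps)) + 1
    mask = labels == keep
    mask = ndimage.binary_fill_holes(mask)
    mask |= seeds  # hard constraint: certain foreground always kept
    mask &= trimap != CERTAIN_BG  # hard constraint: never in certain background
    return mask


def segment_silhouette(image: np.ndarray, trimap: np.ndarray,
                       n_iters: int = DEFAULT_GRAPHCUT_ITERS,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Extract the binary subject silhouette by iterative graph cut.

    ``image`` is (H, W, 3) uint8/float RGB; ``trimap`` the seed raster.
    Certain-foreground pixels are always foreground in the result,
    certain-background pixels never are. The raw cut is post-processed:
    only the connected component overlapping the seeds is kept and its
    holes are filled, so later boundary searches never hit speckle.
    """
    from .graphcut import grabcut_masks  # deferred: heavy imports

    trimap = np.asarray(trimap)
    if image.shape[:2] != trimap.shape:
        raise SegmentationError("image and trimap shapes differ")
    if not (trimap == CERTAIN_FG).any():
        raise SegmentationError("trimap has no certain-foreground seed")
    if not (trimap == CERTAIN_BG).any():
        raise SegmentationError("trimap has no certain-background pixel")

    raw = grabcut_masks(image, trimap, n_iters=n_iters, rng=rng)
    mask = _postprocess(raw, trimap)
    if not mask.any():
        raise SegmentationError("empty silhouette after segmentation")
    return mask


def save_mask_png(mask: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def save_trimap_png(trimap: np.ndarray, path) -> None:
    """Paletted PNG: red = certain background, yellow = probable
    background, green = certain foreground."""
    from PIL import Image

    img = Image.fromarray(trimap.astype(np.uint8), mode="P")
    palette = [0] * 768
    palette[CERTAIN_BG * 3: CERTAIN_BG * 3 + 3] = [220, 40, 40]
    palette[PROBABLE_BG * 3: PROBABLE_BG * 3 + 3] = [235, 220, 60]
    palette[CERTAIN_FG * 3: CERTAIN_FG * 3 + 3] = [60, 200, 80]
    img.putpalette(palette)
    img.save(path)
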