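"""Sagittal view landmark construction: S-KPS = {C7, FC, L5, MA}.

C7, L5 and FC are spinous landmarks on the *back contour*, so this view
needs the silhouette mask in addition to the keypoints:

* A helper point ``A`` is placed on the ear-shoulder segment at K2%
  (default 40) of the way up from the shoulder; C7 is found by marching
  from A, perpendicular to the ear-shoulder segment, toward the back,
  and taking the last silhouette pixel.
* L5' is built exactly like the frontal L5 (hip displaced up by K1% of
  the leg length, one-sided when only one side is visible); L5 is the
  last silhouette pixel marching horizontally backwards from L5'.
* FC, the fulcrum of the spine flexion, is the silhouette point on the
  posterior side of the C7-L5 line at maximal perpendicular distance
  from it.
* MA is the ankle keypoint of the visible side (lateral malleolus proxy).

The formulas are written for a right-facing subject; left-facing images
substitute the mirrored keypoints automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from ._geometry import perp, signed_line_distance, unit
from .errors import GeometryError, LandmarkError, MissingKeypointError
from .keypoints import Keypoint2D, PoseKeypoints

logger = logging.getLogger(__name__)

DEFAULT_K2 = 40.0
MARCH_STEP = 0.5  # px, sub-pixel march resolution

_SIDE_CHAIN = {
    "right": ("REar", "RSH", "RH", "RK", "RA"),
    "left": ("LEar", "LSH", "LH", "LK", "LA"),
}


@dataclass
class SagittalLandmarks:
    C7: Keypoint2D
    L5: Keypoint2D
    FC: Keypoint2D
    MA: Keypoint2D
    A: Keypoint2D          # intermediate ear-shoulder point
    L5_prime: Keypoint2D   # intermediate pre-march L5
    posterior_dir: np.ndarray = None
    fc_distance: float = 0.0
    side: str = "right"

    def as_dict(self) -> Dict[str, Keypoint2D]:
        return {"C7": self.C7, "L5": self.L5, "FC": self.FC, "MA": self.MA,
                "A": self.A, "L5_prime": self.L5_prime}


def detect_side_and_posterior(keypoints: PoseKeypoints) -> Tuple[str, np.ndarray]:
    """Which body side faces the camera, and the backwards direction.

    The visible side is the one whose ear-shoulder-hip-knee-ankle chain
    is complete with the higher summed confidence. The posterior
    direction is the horizontal unit vector pointing from the face
    (nose/eye centroid) toward the ear, i.e. away from where the
    subject looks.
    """
    sums = {}
    for side, chain in _SIDE_CHAIN.items():
        if keypoints.has(*chain):
            sums[side] = sum(keypoints[n].confidence for n in chain)
    if not sums:
        raise MissingKeypointError(
            [n for chain in _SIDE_CHAIN.values() for n in chain]
        )
    side = max(sums, key=lambda s: (sums[s], s == "right"))
    ear = keypoints[_SIDE_CHAIN[side][0]]
    face = [keypoints[n] for n in ("N", "REye", "LEye") if keypoints.has(n)]
    if not face:
        raise MissingKeypointError(["N", "REye", "LEye"])
    face_x = float(np.mean([kp.x for kp in face]))
    dx = ear.x - face_x
    if dx == 0:
        raise GeometryError("cannot orient posterior direction: ear above face centroid")
    posterior = np.array([1.0 if dx > 0 else -1.0, 0.0])
    logger.debug("sagittal side=%s posterior_dir=%s", side, posterior)
    return side, posterior


def point_A(keypoints: PoseKeypoints, K2: float = DEFAULT_K2,
            side: str = "right") -> Keypoint2D:
    """A = shoulder + K2/100 * (ear - shoulder), on the neck axis."""
    if not (0 < K2 < 100):
        raise GeometryError(f"K2 must lie in (0, 100), got {K2}")
    ear_n, sh_n = _SIDE_CHAIN[side][0], _SIDE_CHAIN[side][1]
    ear, sh = keypoints.require(ear_n, sh_n)
    if np.allclose(ear.xy, sh.xy):
        raise GeometryError("ear and shoulder coincide; cannot place A")
    a = sh.xy + K2 / 100.0 * (ear.xy - sh.xy)
    return Keypoint2D(float(a[0]), float(a[1]))


def _in_mask(mask: np.ndarray, pt: np.ndarray) -> bool:
    j = int(round(pt[0]))
    i = int(round(pt[1]))
    if i < 0 or j < 0 or i >= mask.shape[0] or j >= mask.shape[1]:
        return False
    return bool(mask[i, j])


def _inside_image(mask: np.ndarray, pt: np.ndarray) -> bool:
    j = int(round(pt[0]))
    i = int(round(pt[1]))
    return 0 <= i < mask.shape[0] and 0 <= j < mask.shape[1]


def _bisect_boundary(mask: np.ndarray, inside: np.ndarray, outside: np.ndarray,
                     n_iter: int = 10) -> np.ndarray:
    """Sub-pixel boundary point between an in-mask and an out-of-mask
    sample: bisection on the membership predicate, returning the in-mask
    side. Keeps every boundary landmark at the same localisation
    convention, so their offsets cancel in the angles."""
    lo, hi = np.asarray(inside, float), np.asarray(outside, float)
    for _ in range(n_iter):
        mid = (lo + hi) / 2.0
        if _in_mask(mask, mid):
            lo = mid
        else:
            hi = mid
    return lo


def march_to_boundary(mask: np.ndarray, start: np.ndarray,
                      direction: np.ndarray, step: float = MARCH_STEP,
                      what: str = "landmark") -> np.ndarray:
    """Last in-mask point marching from ``start`` along ``direction``.

    Sub-pixel steps, then bisection refinement between the last in-mask
    and first out-of-mask samples. Errors if the start is outside the
    mask or the march leaves the image while still inside the mask.
    """
    d = unit(direction)
    pt = np.asarray(start, dtype=float)
    if not _in_mask(mask, pt):
        raise LandmarkError(f"{what}: march start {pt} lies outside the silhouette")
    last = pt.copy()
    max_steps = int(np.hypot(*mask.shape) / step) + 2
    for _ in range(max_steps):
        nxt = last + step * d
        if not _inside_image(mask, nxt):
            raise LandmarkError(
                f"{what}: search ray exits the image while still inside the mask; "
                "re-segment with a larger subject box"
            )
        if not _in_mask(mask, nxt):
            return _bisect_boundary(mask, last, nxt)
        last = nxt
    raise LandmarkError(f"{what}: march did not terminate")  # pragma: no cover


def c7_sagittal(mask: np.ndarray, keypoints: PoseKeypoints, A: Keypoint2D,
                posterior_dir: np.ndarray, side: str = "right") -> Keypoint2D:
    """C7 = last silhouette point from A, perpendicular to ear-shoulder,
    toward the back."""
    ear_n, sh_n = _SIDE_CHAIN[side][0], _SIDE_CHAIN[side][1]
    ear, sh = keypoints.require(ear_n, sh_n)
    n = perp(unit(ear.xy - sh.xy))
    if float(n @ posterior_dir) < 0:
        n = -n
    if float(n @ posterior_dir) == 0:
        raise GeometryError("ear-shoulder segment is horizontal; no posterior normal")
    pt = march_to_boundary(mask, A.xy, n, what="C7")
    return Keypoint2D(float(pt[0]), float(pt[1]))


def l5_sagittal(mask: np.ndarray, keypoints: PoseKeypoints,
                K1: float = 20.0, posterior_dir: Optional[np.ndarray] = None,
                side: str = "right") -> Tuple[Keypoint2D, Keypoint2D]:
    """(L5, L5') on the sagittal view.

    L5' repeats the frontal construction; when the far side's hip/knee
    are occluded the visible side's leg alone is used. L5 is the last
    silhouette pixel marching horizontally backwards from L5'.
    """
    if not (0 < K1 < 100):
        raise GeometryError(f"K1 must lie in (0, 100), got {K1}")
    if posterior_dir is None:
        _, posterior_dir = detect_side_and_posterior(keypoints)
    hips, knees = [], []
    for s in ("right", "left"):
        h_n, k_n = _SIDE_CHAIN[s][2], _SIDE_CHAIN[s][3]
        if keypoints.has(h_n, k_n):
            hips.append(keypoints[h_n].xy)
            knees.append(keypoints[k_n].xy)
    if not hips:
        raise MissingKeypointError(["RH", "RK", "LH", "LK"])
    mh = np.mean(hips, axis=0)
    leg = float(np.mean([np.linalg.norm(h - k) for h, k in zip(hips, knees)]))
    if leg <= 0:
        raise GeometryError("zero leg length; cannot place L5'")
    l5p = mh - np.array([0.0, K1 / 100.0 * leg])
    pt = march_to_boundary(mask, l5p, posterior_dir, what="L5")
    return (Keypoint2D(float(pt[0]), float(pt[1])),
            Keypoint2D(float(l5p[0]), float(l5p[1])))


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(n, 2) x,y coordinates of mask pixels on the silhouette boundary
    (4-connectivity; image-edge mask pixels count as boundary)."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
    edge = mask & ~eroded
    ii, jj = np.nonzero(edge)
    return np.stack([jj, ii], axis=-1).astype(float)


def fc_search(mask: np.ndarray, C7: Keypoint2D, L5: Keypoint2D,
              posterior_dir: np.ndarray, method: str = "boundary") -> Tuple[Keypoint2D, float]:
    """Fulcrum of the spine flexion.

    ``boundary`` (default): the silhouette boundary pixel strictly on
    the posterior side of the infinite C7-L5 line with the largest
    perpendicular distance; ties go to smaller y, then smaller x.
    ``ray``: perpendicular ray-marching from sample points of the C7-L5
    segment (kept for fidelity with the original search description;
    equivalent up to rasterisation).
    """
    if np.allclose(C7.xy, L5.xy):
        raise GeometryError("C7 and L5 coincide; the fulcrum line is undefined")
    if not mask.any():
        raise LandmarkError("empty silhouette; cannot search for FC")
    if method == "ray":
        return _fc_ray_march(mask, C7, L5, posterior_dir)
    pts = boundary_pixels(mask)
    d = signed_line_distance(pts, C7.xy, L5.xy, posterior_dir)
    posterior = d > 1e-9
    if not posterior.any():
        raise LandmarkError("no silhouette boundary strictly posterior of the C7-L5 line")
    pts, d = pts[posterior], d[posterior]
    dmax = d.max()
    tied = np.nonzero(d == dmax)[0]
    order = np.lexsort((pts[tied, 0], pts[tied, 1]))  # smaller y, then x
    best = pts[tied[order[0]]]
    # refine from the pixel centre to the sub-pixel contour along the
    # posterior normal (same localisation convention as the marches),
    # staying within 1 px of the selected boundary pixel
    n = perp(unit(L5.xy - C7.xy))
    if float(n @ posterior_dir) < 0:
        n = -n
    probe = best.copy()
    for _ in range(2):
        probe = probe + 0.5 * n
        if not _inside_image(mask, probe) or not _in_mask(mask, probe):
            best = _bisect_boundary(mask, best, probe)
            break
    d_best = float(signed_line_distance(best[None, :], C7.xy, L5.xy,
                                        posterior_dir)[0])
    return Keypoint2D(float(best[0]), float(best[1])), d_best


def _fc_ray_march(mask, C7, L5, posterior_dir):
    axis = L5.xy - C7.xy
    n = perp(unit(axis))
    if float(n @ posterior_dir) < 0:
        n = -n
    length = float(np.linalg.norm(axis))
    n_samples = max(2, int(length / MARCH_STEP))
    best, best_d = None, -np.inf
    for t in np.linspace(0.0, 1.0, n_samples):
        start = C7.xy + t * axis
        if not _in_mask(mask, start):
            continue
        try:
            hit = march_to_boundary(mask, start, n, what="FC")
        except LandmarkError:
            continue
        d = float((hit - C7.xy) @ n)
        if d > best_d + 1e-9 or (abs(d - best_d) <= 1e-9 and best is not None
                                 and (hit[1], hit[0]) < (best[1], best[0])):
            best, best_d = hit, d
    if best is None or best_d <= 1e-9:
        raise LandmarkError("no silhouette boundary strictly posterior of the C7-L5 line")
    return Keypoint2D(float(best[0]), float(best[1])), best_d


def ma_sagittal(keypoints: PoseKeypoints, side: str = "right") -> Keypoint2D:
    """The visible side's ankle keypoint, unchanged (malleolus proxy)."""
    ankle_n = _SIDE_CHAIN[side][4]
    (ankle,) = keypoints.require(ankle_n)
    return Keypoint2D(float(ankle.x), float(ankle.y), ankle.confidence)


def augment_sagittal(mask: np.ndarray, keypoints: PoseKeypoints,
                     K1: float = 20.0, K2: float = DEFAULT_K2,
                     fc_method: str = "boundary") -> SagittalLandmarks:
    """Build the full sagittal landmark set from mask + keypoints."""
    side, posterior = detect_side_and_posterior(keypoints)
    a = point_A(keypoints, K2, side)
    c7 = c7_sagittal(mask, keypoints, a, posterior, side)
    l5, l5p = l5_sagittal(mask, keypoints, K1, posterior, side)
    try:
        fc, fc_dist = fc_search(mask, c7, l5, posterior, method=fc_method)
    except LandmarkError:
        # perfectly straight back: no strictly posterior contour; the
        # fulcrum degenerates onto the C7-L5 segment and tCC is 0
        mid = (c7.xy + l5.xy) / 2.0
        fc, fc_dist = Keypoint2D(float(mid[0]), float(mid[1])), 0.0
        logger.info("no posterior contour beyond the C7-L5 line; "
                    "fulcrum degenerates to the segment midpoint (tCC=0)")
    ma = ma_sagittal(keypoints, side)
    logger.debug("sagittal landmarks: C7=%s L5=%s FC=%s (d=%.1f px) MA=%s",
                 c7, l5, fc, fc_dist, ma)
    return SagittalLandmarks(C7=c7, L5=l5, FC=fc, MA=ma, A=a, L5_prime=l5p,
                             posterior_dir=posterior, fc_distance=fc_dist,
                             side=side)
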