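"""Frontal (posterior) view landmark construction: F-KPS = {C7, L5, MA}.

All three landmarks come from the pose keypoints by pure geometry -- no
silhouette is needed on this view:

* C7 sits at the base of the neck, located as the crossing of the two
  contralateral shoulder-to-ear diagonals (left shoulder to right ear,
  right shoulder to left ear), which physically intersect there.
* L5 lies on the image-vertical line through the hip mid-point MH,
  displaced toward the head by K1% (default 20) of the mean hip-to-knee
  distance -- placing it just under the iliac-crest line.
* MA is the mid-point between the two ankle keypoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from ._geometry import segment_intersection
from .errors import GeometryError
from .keypoints import Keypoint2D, PoseKeypoints

DEFAULT_K1 = 20.0


@dataclass
class FrontalLandmarks:
    C7: Keypoint2D
    L5: Keypoint2D
    MA: Keypoint2D
    MH: Keypoint2D  # intermediate hip mid-point, kept for audit

    def as_dict(self) -> Dict[str, Keypoint2D]:
        return {"C7": self.C7, "L5": self.L5, "MA": self.MA, "MH": self.MH}


def c7_frontal(keypoints: PoseKeypoints) -> Keypoint2D:
    """C7 as the intersection of the contralateral shoulder-ear diagonals.

    The crossing may fall marginally beyond a segment endpoint when the
    detector jitters the shoulder/ear keypoints, so 25% slack on the
    containment check is allowed; configurations whose diagonals cross
    far from the neck (or not at all) still raise a geometry error.
    """
    lsh, rsh, lear, rear = keypoints.require("LSH", "RSH", "LEar", "REar")
    pt = segment_intersection(lsh.xy, rear.xy, rsh.xy, lear.xy, tol=0.25)
    return Keypoint2D(float(pt[0]), float(pt[1]))


def l5_frontal(keypoints: PoseKeypoints,
               K1: float = DEFAULT_K1) -> Tuple[Keypoint2D, Keypoint2D]:
    """L5 (and the intermediate MH) from the hips and knees.

    MH = midpoint(LH, RH); L5 = MH moved up (decreasing image y) by
    K1/100 of the mean leg segment length |hip - knee|.
    """
    if not (0 < K1 < 100):
        raise GeometryError(f"K1 must lie in (0, 100), got {K1}")
    lh, rh, lk, rk = keypoints.require("LH", "RH", "LK", "RK")
    mh = (lh.xy + rh.xy) / 2.0
    leg = (np.linalg.norm(lh.xy - lk.xy) + np.linalg.norm(rh.xy - rk.xy)) / 2.0
    if leg <= 0:
        raise GeometryError("zero leg length; cannot place L5")
    l5 = mh - np.array([0.0, K1 / 100.0 * leg])  # y-down: up is -y
    return (Keypoint2D(float(l5[0]), float(l5[1])),
            Keypoint2D(float(mh[0]), float(mh[1])))


def ma_frontal(keypoints: PoseKeypoints) -> Keypoint2D:
    """MA = component-wise midpoint of the two ankle keypoints."""
    la, ra = keypoints.require("LA", "RA")
    m = (la.xy + ra.xy) / 2.0
    return Keypoint2D(float(m[0]), float(m[1]))


def augment_frontal(keypoints: PoseKeypoints,
                    K1: float = DEFAULT_K1) -> FrontalLandmarks:
    """Build the full frontal landmark set."""
    c7 = c7_frontal(keypoints)
    l5, mh = l5_frontal(keypoints, K1)
    ma = ma_frontal(keypoints)
    return FrontalLandmarks(C7=c7, L5=l5, MA=ma, MH=mh)
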