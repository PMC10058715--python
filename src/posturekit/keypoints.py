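"""Pose-keypoint containers and I/O.

The canonical skeleton is the 25-keypoint ("BODY25") model emitted by
off-the-shelf human-pose estimators as JSON: ``people[*].pose_keypoints_2d``
holds a flat stream of 75 floats (x, y, confidence per keypoint).
posturekit never runs a network itself -- keypoints are an input.

Coordinates are pixels, origin top-left, y increasing downward, 0-based,
sub-pixel allowed. A keypoint with confidence 0 is *missing* and its
coordinates are undefined; operations that need a missing keypoint raise
:class:`~posturekit.errors.MissingKeypointError` rather than imputing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .errors import EmptyDetectionError, FormatError, MissingKeypointError

logger = logging.getLogger(__name__)

#: BODY25 keypoint names, in slot order of the JSON dialect.
BODY25_NAMES: tuple = (
    "N",        # 0  nose
    "NECK",     # 1  neck / upper-chest centroid
    "RSH",      # 2  right shoulder
    "RE",       # 3  right elbow
    "RW",       # 4  right wrist
    "LSH",      # 5  left shoulder
    "LE",       # 6  left elbow
    "LW",       # 7  left wrist
    "P",        # 8  pelvis / mid-hip
    "RH",       # 9  right hip
    "RK",       # 10 right knee
    "RA",       # 11 right ankle
    "LH",       # 12 left hip
    "LK",       # 13 left knee
    "LA",       # 14 left ankle
    "REye",     # 15
    "LEye",     # 16
    "REar",     # 17
    "LEar",     # 18
    "LBigToe",  # 19
    "LSmallToe",# 20
    "LHeel",    # 21
    "RBigToe",  # 22
    "RSmallToe",# 23
    "RHeel",    # 24
)

VIEWS = ("frontal", "sagittal")


@dataclass(frozen=True)
class Keypoint2D:
    """One 2D keypoint: pixel coordinates plus detector confidence in [0,1]."""

    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise FormatError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def missing(self) -> bool:
        return self.confidence == 0.0

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


MISSING = Keypoint2D(float("nan"), float("nan"), 0.0)


@dataclass
class PoseKeypoints:
    """The 25 named keypoint slots of one person in one image."""

    points: Dict[str, Keypoint2D]
    view: str = "frontal"
    image_width: int = 0
    image_height: int = 0

    def __post_init__(self):
        if self.view not in VIEWS:
            raise FormatError(f"view must be one of {VIEWS}, got {self.view!r}")
        full = {name: MISSING for name in BODY25_NAMES}
        for name, kp in self.points.items():
            if name not in full:
                raise FormatError(f"unknown keypoint name {name!r}")
            full[name] = kp
        self.points = full

    def __getitem__(self, name: str) -> Keypoint2D:
        return self.points[name]

    def has(self, *names: str) -> bool:
        return all(not self.points[n].missing for n in names)

    def require(self, *names: str) -> List[Keypoint2D]:
        absent = [n for n in names if self.points[n].missing]
        if absent:
            raise MissingKeypointError(absent)
        return [self.points[n] for n in names]

    def present_names(self) -> List[str]:
        return [n for n in BODY25_NAMES if not self.points[n].missing]

    def present_xy(self) -> np.ndarray:
        """(n, 2) array of the present keypoints' coordinates."""
        names = self.present_names()
        if not names:
            return np.zeros((0, 2))
        return np.array([[self.points[n].x, self.points[n].y] for n in names])

    def bbox_area(self) -> float:
        xy = self.present_xy()
        if len(xy) == 0:
            return 0.0
        w = float(xy[:, 0].max() - xy[:, 0].min())
        h = float(xy[:, 1].max() - xy[:, 1].min())
        return w * h


@dataclass
class SubjectRecord:
    """One analysed subject image plus optional study covariates."""

    image_path: str
    keypoints: PoseKeypoints
    bmi: Optional[float] = None  # kg/m^2
    ground_truth_angles: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.bmi is not None and not self.bmi > 0:
            raise FormatError(f"bmi must be positive, got {self.bmi}")


def _clamp_keypoint(name, kp, width, height):
    if kp.missing or width <= 0 or height <= 0:
        return kp
    x = min(max(kp.x, 0.0), math.nextafter(float(width), 0.0))
    y = min(max(kp.y, 0.0), math.nextafter(float(height), 0.0))
    if x != kp.x or y != kp.y:
        logger.warning(
            "keypoint %s at (%.1f, %.1f) outside image %dx%d; clamped",
            name, kp.x, kp.y, width, height,
        )
        return Keypoint2D(x, y, kp.confidence)
    return kp


def parse_flat_triplets(values: Sequence[float], view: str = "frontal",
                        image_width: int = 0, image_height: int = 0) -> PoseKeypoints:
    """Build PoseKeypoints from the 75-float flat (x, y, c) stream."""
    vals = list(values)
    if len(vals) != 3 * len(BODY25_NAMES):
        raise FormatError(
            f"expected {3 * len(BODY25_NAMES)} floats, got {len(vals)}"
        )
    pts = {}
    for i, name in enumerate(BODY25_NAMES):
        x, y, c = vals[3 * i: 3 * i + 3]
        if c == 0:
            pts[name] = MISSING
        else:
            kp = Keypoint2D(float(x), float(y), float(min(max(c, 0.0), 1.0)))
            pts[name] = _clamp_keypoint(name, kp, image_width, image_height)
    return PoseKeypoints(pts, view=view,
                         image_width=image_width, image_height=image_height)


def read_pose_json(path, person_index: int = 0, view: str = "frontal",
                   image_width: int = 0, image_height: int = 0) -> PoseKeypoints:
    """Read one person's keypoints from a pose-estimator JSON file.

    ``people[person_index].pose_keypoints_2d`` must hold 75 floats.
    Image dimensions are taken from the arguments (callers usually read
    them from the image itself).
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse pose JSON {path}: {exc}") from exc
    people = doc.get("people")
    if not isinstance(people, list):
        raise FormatError(f"{path}: missing 'people' list")
    if len(people) == 0:
        raise EmptyDetectionError(f"{path}: no people detected")
    if not (0 <= person_index < len(people)):
        raise IndexError(
            f"person_index {person_index} out of range (file has {len(people)})"
        )
    triplets = people[person_index].get("pose_keypoints_2d")
    if triplets is None:
        raise FormatError(f"{path}: person {person_index} lacks pose_keypoints_2d")
    return parse_flat_triplets(triplets, view=view,
                               image_width=image_width, image_height=image_height)


def read_all_people(path, view: str = "frontal",
                    image_width: int = 0, image_height: int = 0) -> List[PoseKeypoints]:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse pose JSON {path}: {exc}") from exc
    people = doc.get("people") or []
    if not people:
        raise EmptyDetectionError(f"{path}: no people detected")
    return [
        parse_flat_triplets(p.get("pose_keypoints_2d", []), view=view,
                            image_width=image_width, image_height=image_height)
        for p in people
    ]


def select_subject(people: List[PoseKeypoints]) -> PoseKeypoints:
    """Pick the person with the largest bounding box of present keypoints.

    Photographs follow a single-subject protocol; stray background
    detections are smaller. Ties keep the lowest index (deterministic).
    """
    if not people:
        raise EmptyDetectionError("no people to select from")
    areas = [p.bbox_area() for p in people]
    return people[int(np.argmax(areas))]


def write_pose_json(keypoints: PoseKeypoints, path) -> None:
    """Write PoseKeypoints back to the 25-keypoint JSON dialect."""
    flat: List[float] = []
    for name in BODY25_NAMES:
        kp = keypoints[name]
        if kp.missing:
            flat += [0.0, 0.0, 0.0]
        else:
            flat += [float(kp.x), float(kp.y), float(kp.confidence)]
    doc = {"version": 1.3, "people": [{"person_id": [-1], "pose_keypoints_2d": flat}]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def write_landmarks(landmarks: Dict[str, Keypoint2D], path, view: str) -> None:
    """Write augmented landmarks as JSON: named pixel coordinates + view.

    Landmarks absent for a view (e.g. FC on frontal images) are simply
    omitted, never null-filled. NaN coordinates are rejected.
    """
    if view not in VIEWS:
        raise FormatError(f"view must be one of {VIEWS}")
    out = {"view": view, "landmarks": {}}
    for name, kp in landmarks.items():
        if kp is None:
            continue
        if not (math.isfinite(kp.x) and math.isfinite(kp.y)):
            raise FormatError(f"landmark {name} has non-finite coordinates")
        out["landmarks"][name] = {"x": float(kp.x), "y": float(kp.y),
                                  "confidence": float(kp.confidence)}
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=1)
    except OSError as exc:
        raise OSError(f"cannot write landmark file {path}: {exc}") from exc


def read_landmarks(path):
    """Inverse of :func:`write_landmarks`. Returns (landmarks dict, view)."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse landmark file {path}: {exc}") from exc
    if "landmarks" not in doc or "view" not in doc:
        raise FormatError(f"{path}: not a landmark file")
    lm = {
        name: Keypoint2D(float(d["x"]), float(d["y"]),
                         float(d.get("confidence", 1.0)))
        for name, d in doc["landmarks"].items()
    }
    return lm, doc["view"]
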