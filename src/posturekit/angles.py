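"""Postural angle measurement and classification.

All three axial postural abnormalities are measured as *external* angles
at a landmark apex: 180 degrees minus the interior angle between the two
limbs meeting there. A perfectly straight, upright posture therefore
measures 0 degrees, and consensus cut-offs compare directly:

* Pisa syndrome (PS) -- lateral trunk flexion, frontal(posterior) view:
  apex L5, limbs to the ankle mid-point (MA) and to C7. Pathological > 10.
* Lumbar camptocormia (lCC) -- sagittal view: apex L5, limbs to the
  visible lateral malleolus (MA) and to C7. Pathological > 30 *and* hip
  flexion; hip flexion is not assessable from one photograph, so reports
  carry ``hip_flexion_assessed = False``.
* Thoracic camptocormia (tCC) -- sagittal view: apex at the flexion
  fulcrum FC, limbs to L5 and to C7. Pathological > 45.

Cut-offs are strict (an angle exactly at the threshold is negative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import GeometryError
from .keypoints import Keypoint2D

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"ps": 10.0, "lcc": 30.0, "tcc": 45.0}


def external_angle(apex, p, q) -> float:
    """External angle at ``apex`` of the triangle (p, apex, q), degrees.

    180 - arccos of the normalised dot product of the two limb vectors;
    0 when p, apex, q are collinear with the apex between them. If p and
    q lie on the same ray from the apex the value is 180, which is
    anatomically impossible and logged as a warning.
    """
    apex = apex.xy if isinstance(apex, Keypoint2D) else np.asarray(apex, float)
    p = p.xy if isinstance(p, Keypoint2D) else np.asarray(p, float)
    q = q.xy if isinstance(q, Keypoint2D) else np.asarray(q, float)
    u = p - apex
    v = q - apex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("zero-length limb at the angle apex")
    cosang = float(np.clip((u @ v) / (nu * nv), -1.0, 1.0))
    ext = 180.0 - math.degrees(math.acos(cosang))
    if ext >= 180.0 - 1e-9:
        logger.warning(
            "external angle of 180 deg (limbs on the same ray): anatomically implausible"
        )
    return ext


@dataclass
class AngleReport:
    """Measured angles, classification flags and the landmarks used."""

    view: str
    ps_deg: Optional[float] = None
    lcc_deg: Optional[float] = None
    tcc_deg: Optional[float] = None
    flags: Dict[str, bool] = field(default_factory=dict)
    hip_flexion_assessed: bool = False
    landmark_snapshot: Dict[str, Keypoint2D] = field(default_factory=dict)

    def angles(self) -> Dict[str, float]:
        out = {}
        for name in ("ps", "lcc", "tcc"):
            v = getattr(self, f"{name}_deg")
            if v is not None:
                out[name] = v
        return out

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {"view": self.view}
        for name in ("ps", "lcc", "tcc"):
            v = getattr(self, f"{name}_deg")
            row[f"{name}_deg"] = None if v is None else round(v, 1)
            row[f"{name}_flag"] = self.flags.get(name)
        row["hip_flexion_assessed"] = self.hip_flexion_assessed
        for lname, kp in self.landmark_snapshot.items():
            row[f"{lname}_x"] = round(float(kp.x), 2)
            row[f"{lname}_y"] = round(float(kp.y), 2)
        return row


def measure_ps(frontal_landmarks) -> float:
    """Pisa syndrome angle: apex L5, limbs toward MA and C7."""
    return external_angle(frontal_landmarks.L5, frontal_landmarks.MA,
                          frontal_landmarks.C7)


def measure_lcc(sagittal_landmarks) -> float:
    """Lumbar camptocormia angle: apex L5, limbs toward the malleolus
    proxy (MA) and C7. Hip flexion is not assessed from the image."""
    return external_angle(sagittal_landmarks.L5, sagittal_landmarks.MA,
                          sagittal_landmarks.C7)


def measure_tcc(sagittal_landmarks) -> float:
    """Thoracic camptocormia angle: apex at the flexion fulcrum FC,
    limbs toward L5 and C7."""
    return external_angle(sagittal_landmarks.FC, sagittal_landmarks.L5,
                          sagittal_landmarks.C7)


def classify(report: AngleReport,
             thresholds: Optional[Dict[str, float]] = None) -> Dict[str, bool]:
    """Strict > comparison of each measured angle against its cut-off.

    The lCC flag reflects the image-measurable clause only (the
    companion hip-flexion requirement is reported as unassessed).
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update({k.lower(): float(v) for k, v in thresholds.items()})
    flags = {}
    for name, value in report.angles().items():
        flags[name] = bool(value > th[name])
    report.flags = flags
    report.hip_flexion_assessed = False
    return flags


def report_frontal(landmarks, thresholds=None) -> AngleReport:
    rep = AngleReport(view="frontal", ps_deg=measure_ps(landmarks),
                      landmark_snapshot=landmarks.as_dict())
    classify(rep, thresholds)
    return rep


def report_sagittal(landmarks, thresholds=None) -> AngleReport:
    rep = AngleReport(view="sagittal",
                      lcc_deg=measure_lcc(landmarks),
                      tcc_deg=measure_tcc(landmarks),
                      landmark_snapshot=landmarks.as_dict())
    classify(rep, thresholds)
    return rep
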