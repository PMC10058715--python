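"""End-to-end measurement: image + keypoints -> angles and flags.

Stages: subject box -> trimap -> graph-cut silhouette -> view-specific
landmark augmentation -> angle measurement -> cut-off classification.
The frontal landmarks are purely geometric; the silhouette is still
extracted there for the cover-factor covariates.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import angles as angles_mod
from . import silhouette as sil
from . import stats as stats_mod
from .errors import PostureError
from .frontal import augment_frontal
from .keypoints import PoseKeypoints, read_all_people, select_subject, write_landmarks
from .sagittal import augment_sagittal, detect_side_and_posterior

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the validated operating point."""

    K1: float = 20.0                    # % of leg length: hip midpoint -> L5
    K2: float = 40.0                    # % of shoulder->ear distance: point A
    band_thickness_scale: float = sil.DEFAULT_BAND_SCALE
    box_margin_frac: float = sil.DEFAULT_BOX_MARGIN
    min_width_frac: float = sil.DEFAULT_MIN_WIDTH_FRAC
    graphcut_iters: int = sil.DEFAULT_GRAPHCUT_ITERS
    thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(angles_mod.DEFAULT_THRESHOLDS))
    fc_method: str = "boundary"
    seed: int = 0
    debug_overlay: bool = False
    output_dir: str = "."

    def __post_init__(self):
        for k in ("K1", "K2"):
            v = getattr(self, k)
            if not (0 < v < 100):
                raise ValueError(f"{k} must lie in (0, 100), got {v}")
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


def extract_mask(image: np.ndarray, keypoints: PoseKeypoints,
                 config: Optional[RunConfig] = None,
                 side: Optional[str] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Run box -> trimap -> graph cut; returns (mask, trimap)."""
    config = config or RunConfig()
    box = sil.subject_box(keypoints, config.box_margin_frac,
                          image_shape=image.shape[:2],
                          min_width_frac=config.min_width_frac)
    trimap = sil.build_trimap(image.shape[:2], keypoints, box,
                              config.band_thickness_scale, side=side)
    rng = np.random.default_rng(config.seed)
    mask = sil.segment_silhouette(image, trimap, config.graphcut_iters, rng=rng)
    return mask, trimap


def measure_image(image: np.ndarray, keypoints: PoseKeypoints, view: str,
                  config: Optional[RunConfig] = None,
                  mask: Optional[np.ndarray] = None):
    """Measure one image. Returns (AngleReport, landmarks, mask)."""
    config = config or RunConfig()
    side = None
    if view == "sagittal":
        side, _ = detect_side_and_posterior(keypoints)
    if mask is None:
        mask, _ = extract_mask(image, keypoints, config, side=side)
    if view == "frontal":
        landmarks = augment_frontal(keypoints, K1=config.K1)
        report = angles_mod.report_frontal(landmarks, config.thresholds)
    else:
        landmarks = augment_sagittal(mask, keypoints, K1=config.K1,
                                     K2=config.K2, fc_method=config.fc_method)
        report = angles_mod.report_sagittal(landmarks, config.thresholds)
    return report, landmarks, mask


def measure_files(image_path, keypoints_path, view,
                  config: Optional[RunConfig] = None,
                  out_dir: Optional[str] = None, stem: Optional[str] = None):
    """File-level wrapper: read inputs, measure, write artefacts.

    Writes ``<stem>_landmarks.json``, ``<stem>_report.json`` and
    ``<stem>_report.csv`` into ``out_dir`` (plus mask/overlay PNGs when
    debug_overlay is on). Returns the AngleReport.
    """
    from PIL import Image

    config = config or RunConfig()
    out_dir = out_dir or config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    image = np.asarray(Image.open(image_path).convert("RGB"))
    people = read_all_people(keypoints_path, view=view,
                             image_width=image.shape[1],
                             image_height=image.shape[0])
    keypoints = select_subject(people)
    report, landmarks, mask = measure_image(image, keypoints, view, config)

    stem = stem or os.path.splitext(os.path.basename(image_path))[0]
    write_landmarks(landmarks.as_dict(), os.path.join(out_dir, f"{stem}_landmarks.json"),
                    view=view)
    row = {"image": os.path.basename(image_path), **report.to_row()}
    with open(os.path.join(out_dir, f"{stem}_report.json"), "w", encoding="utf-8") as fh:
        json.dump(row, fh, indent=1, sort_keys=True)
    pd.DataFrame([row]).to_csv(os.path.join(out_dir, f"{stem}_report.csv"), index=False)
    if config.debug_overlay:
        sil.save_mask_png(mask, os.path.join(out_dir, f"{stem}_mask.png"))
        save_overlay(image, keypoints, landmarks,
                     os.path.join(out_dir, f"{stem}_overlay.png"))
    return report


def save_overlay(image, keypoints, landmarks, path):
    """Debug rendering: keypoints, landmarks and construction lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 6))
    ax.imshow(image)
    xy = keypoints.present_xy()
    ax.scatter(xy[:, 0], xy[:, 1], s=10, c="cyan", label="pose keypoints")
    lm = landmarks.as_dict()
    for name, kp in lm.items():
        ax.scatter([kp.x], [kp.y], s=30, c="red")
        ax.annotate(name, (kp.x, kp.y), color="yellow", fontsize=8)
    for a, b in (("MA", "L5"), ("L5", "C7")):
        if a in lm and b in lm:
            ax.plot([lm[a].x, lm[b].x], [lm[a].y, lm[b].y], "y-", lw=1)
    if "FC" in lm:
        for other in ("L5", "C7"):
            ax.plot([lm["FC"].x, lm[other].x], [lm["FC"].y, lm[other].y],
                    "r--", lw=1)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def measure_manifest(manifest: pd.DataFrame, config: Optional[RunConfig] = None,
                     use_true_mask: bool = False) -> pd.DataFrame:
    """Measure every fixture of a battery manifest.

    Adds the measured ``<abn>_deg`` columns and the image-characteristic
    covariates to a copy of the manifest. With ``use_true_mask`` the
    manifest's mask files are used directly (isolating the landmark and
    angle stages); otherwise each mask is extracted by graph cut.
    """
    from PIL import Image

    config = config or RunConfig()
    rows = []
    for _, rec in manifest.iterrows():
        image = np.asarray(Image.open(rec["image_path"]).convert("RGB"))
        people = read_all_people(rec["keypoints_path"], view=rec["view"],
                                 image_width=image.shape[1],
                                 image_height=image.shape[0])
        keypoints = select_subject(people)
        mask = None
        if use_true_mask:
            mask = np.asarray(Image.open(rec["mask_path"]).convert("L")) > 127
        out = dict(rec)
        try:
            report, _, mask = measure_image(image, keypoints, rec["view"],
                                            config, mask=mask)
        except PostureError as exc:
            logger.warning("measurement failed for %s: %s", rec["image_path"], exc)
            rows.append(out)
            continue
        for abn, val in report.angles().items():
            out[f"{abn}_deg"] = val
            out[f"{abn}_flag"] = report.flags.get(abn)
        chars = stats_mod.image_characteristics(image, mask)
        for key in ("cover_w", "cover_h", "cover_area",
                    "hue_mean", "sat_mean", "val_mean"):
            out[key] = getattr(chars, key)
        out["area"] = chars.area
        rows.append(out)
    return pd.DataFrame(rows)
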