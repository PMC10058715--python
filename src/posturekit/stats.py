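"""Robustness (correlation) analysis of the posture measurements.

For each abnormality, the measured angle -- or, when ground truth is
available, the measurement error (measured minus ground truth) -- is
correlated against subject anthropometry (BMI), image size (width,
height, area), subject cover factors (bounding-box ratios), and image
colour characteristics (hue/saturation/value summaries). For every
covariate x abnormality pair the sample Pearson coefficient R and its
two-sided p value from the t distribution with n - 2 degrees of freedom
are reported; no multiple-testing correction is applied by default
(each raw p is compared to 0.05), with an optional Bonferroni switch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import FormatError, GeometryError

logger = logging.getLogger(__name__)

#: covariates of the robustness analysis, in reporting order
COVARIATES = (
    "bmi", "width", "height", "area",
    "cover_w", "cover_h", "cover_area",
    "hue_mean", "sat_mean", "val_mean",
)
ABNORMALITY_VIEW = {"ps": "frontal", "lcc": "sagittal", "tcc": "sagittal"}


@dataclass(frozen=True)
class ImageCharacteristics:
    """Per-image covariates: geometry, cover factors, colour summary."""

    width: int
    height: int
    cover_w: float
    cover_h: float
    cover_area: float
    hue_mean: float      # degrees in [0, 360)
    sat_mean: float      # [0, 1]
    val_mean: float      # [0, 1]
    hue_var: float = float("nan")
    sat_var: float = float("nan")
    val_var: float = float("nan")

    @property
    def area(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class CorrelationResult:
    covariate: str
    abnormality: str
    R: float
    p: float
    n: int


def cover_factors(mask: np.ndarray, image_dims: Optional[Tuple[int, int]] = None):
    """(cover_w, cover_h, cover_area): tight mask bounding box over image.

    The bounding box (rather than the pixel count) keeps the width and
    height ratios well defined.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FormatError("empty mask has no cover factors")
    H, W = mask.shape if image_dims is None else (image_dims[1], image_dims[0])
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    bw, bh = int(c1 - c0 + 1), int(r1 - r0 + 1)
    return bw / W, bh / H, (bw * bh) / (W * H)


def hsv_summary(image: np.ndarray):
    """(hue_mean_deg, sat_mean, val_mean) of an RGB image.

    Hue is circular, so its mean is the argument of the mean unit
    phasor; for a desaturated (grey) image the hue phasor vanishes and
    the hue mean is reported as 0. S and V are plain arithmetic means.
    """
    from skimage.color import rgb2hsv

    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise FormatError("hsv_summary expects an (H, W, 3) RGB image")
    hsv = rgb2hsv(img)
    ang = hsv[..., 0] * 2.0 * np.pi
    z = np.exp(1j * ang).mean()
    hue = math.degrees(np.angle(z)) % 360.0 if abs(z) > 1e-12 else 0.0
    return float(hue), float(hsv[..., 1].mean()), float(hsv[..., 2].mean())


def hsv_variances(image: np.ndarray):
    """Circular hue variance (1 - |mean phasor|) and S/V variances."""
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(np.asarray(image))
    z = np.exp(1j * hsv[..., 0] * 2.0 * np.pi).mean()
    return float(1.0 - abs(z)), float(hsv[..., 1].var()), float(hsv[..., 2].var())


def image_characteristics(image: np.ndarray, mask: np.ndarray) -> ImageCharacteristics:
    H, W = np.asarray(image).shape[:2]
    cw, ch, ca = cover_factors(mask, (W, H))
    hue, sat, val = hsv_summary(image)
    hv, sv, vv = hsv_variances(image)
    return ImageCharacteristics(width=W, height=H, cover_w=cw, cover_h=ch,
                                cover_area=ca, hue_mean=hue, sat_mean=sat,
                                val_mean=val, hue_var=hv, sat_var=sv, val_var=vv)


def pearson(x, y) -> Tuple[float, float]:
    """Sample Pearson correlation and its two-sided significance.

    R from the centred cross-moments; p from t = R sqrt((n-2)/(1-R^2))
    against the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatError("pearson expects two equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise FormatError(f"pearson needs n >= 3, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise FormatError("pearson inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise GeometryError("correlation undefined for a constant vector")
    r = float(xc @ yc) / (sx * sy)
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, min(1.0, p)


def robustness_table(records: pd.DataFrame, use_error: bool = False,
                     covariates: Sequence[str] = COVARIATES,
                     bonferroni: bool = False,
                     plot_dir: Optional[str] = None) -> pd.DataFrame:
    """Covariate x abnormality grid of Pearson correlations.

    ``records`` needs one row per image with an ``<abn>_deg`` column per
    measured abnormality, the covariate columns, and (when ``use_error``)
    ``true_<abn>_deg`` ground truth; the correlated quantity is then the
    error, measured minus ground truth. Rows missing a covariate are
    excluded pairwise (logged). Returns a tidy DataFrame
    (covariate, abnormality, R, p, n, significant).
    """
    if "area" in covariates and "area" not in records.columns and \
            {"width", "height"} <= set(records.columns):
        records = records.assign(area=records["width"] * records["height"])
    rows: List[CorrelationResult] = []
    present_abn = [a for a in ABNORMALITY_VIEW if f"{a}_deg" in records.columns
                   and records[f"{a}_deg"].notna().any()]
    if not present_abn:
        raise FormatError("no measured abnormality columns in records")
    for abn in present_abn:
        y_col = records[f"{abn}_deg"].astype(float)
        if use_error:
            gt_col = f"true_{abn}_deg"
            if gt_col not in records.columns:
                raise FormatError(f"use_error requires column {gt_col}")
            y_col = y_col - records[gt_col].astype(float)
        for cov in covariates:
            if cov not in records.columns:
                logger.warning("covariate %s absent; skipped", cov)
                continue
            sub = pd.DataFrame({"x": records[cov], "y": y_col}).dropna()
            excluded = len(records) - len(sub)
            if excluded:
                logger.info("%s vs %s: %d records excluded pairwise",
                            cov, abn, excluded)
            if len(sub) < 3:
                raise FormatError(
                    f"too few records ({len(sub)}) to correlate {cov} with {abn}"
                )
            r, p = pearson(sub["x"].to_numpy(), sub["y"].to_numpy())
            rows.append(CorrelationResult(cov, abn, r, p, len(sub)))
    table = pd.DataFrame([r.__dict__ for r in rows])
    alpha = 0.05
    m = len(table) if bonferroni else 1
    table["significant"] = table["p"] < alpha / m
    if plot_dir is not None:
        _scatter_plots(records, table, use_error, plot_dir)
    return table


def _scatter_plots(records, table, use_error, plot_dir):
    """One scatter panel per covariate, abnormalities colour-coded."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(plot_dir, exist_ok=True)
    colors = {"lcc": "tab:red", "tcc": "tab:green", "ps": "tab:blue"}
    kind = "error" if use_error else "angle"
    for cov in table["covariate"].unique():
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for abn in table.loc[table["covariate"] == cov, "abnormality"]:
            y = records[f"{abn}_deg"].astype(float)
            if use_error:
                y = y - records[f"true_{abn}_deg"].astype(float)
            sub = pd.DataFrame({"x": records[cov], "y": y}).dropna()
            row = table[(table.covariate == cov) & (table.abnormality == abn)].iloc[0]
            ax.scatter(sub["x"], sub["y"], s=14, alpha=0.7, color=colors[abn],
                       label=f"{abn.upper()}: R={row.R:.2f}, p={row.p:.3f}")
        ax.set_xlabel(cov)
        ax.set_ylabel(f"{kind} (deg)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(os.path.join(plot_dir, f"{kind}_vs_{cov}.png"), dpi=110)
        plt.close(fig)
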