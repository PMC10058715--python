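"""Seeded iterative colour-model graph cut (GrabCut-style).

Energy: per-pixel data terms from two Gaussian-mixture colour models
(foreground / background), plus a contrast-sensitive smoothness term on
the 4-neighbourhood. The trimap's certain classes are hard-wired with
infinite terminal links; only probable-background pixels are free. The
binary min cut is solved exactly with ``scipy.sparse.csgraph.maximum_flow``
and the colour models are re-fitted on the new labelling for a fixed
number of iterations (or until the labels stop changing).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .silhouette import CERTAIN_BG, CERTAIN_FG, PROBABLE_BG

logger = logging.getLogger(__name__)

GAMMA = 50.0          # smoothness weight, per Boykov-Jolly tradition
CAP_SCALE = 100.0     # float energy -> integer capacity
INF_CAP = np.int32(10 ** 8)
MAX_DATA_TERM = 60.0  # clip for -log likelihoods
GMM_COMPONENTS = 3
GMM_SAMPLES = 4000    # per model per iteration


def _fit_gmm(pixels: np.ndarray, rng: np.random.Generator):
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.mixture import GaussianMixture

    if len(pixels) > GMM_SAMPLES:
        idx = rng.choice(len(pixels), GMM_SAMPLES, replace=False)
        pixels = pixels[idx]
    n_comp = min(GMM_COMPONENTS, max(1, len(pixels)))
    gmm = GaussianMixture(
        n_components=n_comp,
        covariance_type="full",
        reg_covar=1e-4,
        max_iter=60,
        random_state=int(rng.integers(0, 2 ** 31 - 1)),
    )
    with warnings.catch_warnings():
        # noise-free fixtures have fewer distinct colours than components
        warnings.simplefilter("ignore", ConvergenceWarning)
        gmm.fit(pixels)
    return gmm


def _neg_log_likelihood(gmm, pixels: np.ndarray) -> np.ndarray:
    return np.clip(-gmm.score_samples(pixels), 0.0, MAX_DATA_TERM)


def _pairwise_weights(img: np.ndarray):
    """Contrast-sensitive 4-neighbour weights.

    Returns (right_w, down_w): weights between each pixel and its right /
    lower neighbour, gamma * exp(-beta * ||zi - zj||^2).
    """
    dr = np.sum((img[:, 1:] - img[:, :-1]) ** 2, axis=-1)
    dd = np.sum((img[1:, :] - img[:-1, :]) ** 2, axis=-1)
    total = dr.sum() + dd.sum()
    count = dr.size + dd.size
    beta = 0.0 if total <= 0 else 1.0 / (2.0 * total / count)
    return GAMMA * np.exp(-beta * dr), GAMMA * np.exp(-beta * dd)


def _min_cut_foreground(d_fg, d_bg, right_w, down_w, hard_fg, hard_bg):
    """Solve the binary min cut; returns the foreground boolean raster.

    Terminal capacities: source->p pays when p is labelled background,
    so it carries the background data term (and vice versa). Hard seeds
    get an infinite link to their terminal.
    """
    H, W = d_fg.shape
    n = H * W
    source, sink = n, n + 1
    ids = np.arange(n).reshape(H, W)

    src_cap = np.asarray(d_bg * CAP_SCALE, dtype=np.int64)
    snk_cap = np.asarray(d_fg * CAP_SCALE, dtype=np.int64)
    src_cap[hard_fg] = INF_CAP
    snk_cap[hard_fg] = 0
    src_cap[hard_bg] = 0
    snk_cap[hard_bg] = INF_CAP

    rows = [np.full(n, source), ids.ravel()]
    cols = [ids.ravel(), np.full(n, sink)]
    caps = [src_cap.ravel(), snk_cap.ravel()]

    rw = np.asarray(right_w * CAP_SCALE, dtype=np.int64).ravel()
    a, b = ids[:, :-1].ravel(), ids[:, 1:].ravel()
    rows += [a, b]
    cols += [b, a]
    caps += [rw, rw]

    dw = np.asarray(down_w * CAP_SCALE, dtype=np.int64).ravel()
    a, b = ids[:-1, :].ravel(), ids[1:, :].ravel()
    rows += [a, b]
    cols += [b, a]
    caps += [dw, dw]

    graph = sparse.csr_matrix(
        (np.concatenate(caps).astype(np.int32),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 2, n + 2),
    )
    result = maximum_flow(graph, source, sink)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, source, directed=True,
                                return_predecessors=False)
    fg = np.zeros(n + 2, dtype=bool)
    fg[reach] = True
    return fg[:n].reshape(H, W)


def grabcut_masks(image: np.ndarray, trimap: np.ndarray, n_iters: int = 5,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Run the iterative segmentation; returns the raw foreground mask.

    Deterministic for a given ``rng`` state (default: fresh seed-0
    generator, so repeated calls on the same inputs agree bit-for-bit).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None].repeat(3, axis=-1)
    if img.max() > 1.0:
        img = img / 255.0

    # solve only inside the non-certain-background envelope
    inside = trimap != CERTAIN_BG
    if not inside.any():
        raise ValueError("trimap is all certain background")
    ys, xs = np.where(inside)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    # one-pixel border of certain background keeps the cut anchored
    y0, x0 = max(0, y0 - 1), max(0, x0 - 1)
    y1, x1 = min(trimap.shape[0], y1 + 1), min(trimap.shape[1], x1 + 1)

    sub_img = img[y0:y1, x0:x1]
    sub_tri = trimap[y0:y1, x0:x1]
    hard_fg = sub_tri == CERTAIN_FG
    hard_bg = sub_tri == CERTAIN_BG
    unknown = sub_tri == PROBABLE_BG

    pixels = sub_img.reshape(-1, 3)
    right_w, down_w = _pairwise_weights(sub_img)

    alpha = hard_fg.copy()  # current foreground labelling
    for it in range(max(1, n_iters)):
        fg_px = pixels[alpha.ravel()]
        bg_px = pixels[~alpha.ravel()]
        if len(fg_px) == 0 or len(bg_px) == 0:
            break
        gmm_fg = _fit_gmm(fg_px, rng)
        gmm_bg = _fit_gmm(bg_px, rng)
        d_fg = _neg_log_likelihood(gmm_fg, pixels).reshape(sub_img.shape[:2])
        d_bg = _neg_log_likelihood(gmm_bg, pixels).reshape(sub_img.shape[:2])
        new_fg = _min_cut_foreground(d_fg, d_bg, right_w, down_w,
                                     hard_fg, hard_bg)
        new_alpha = hard_fg | (new_fg & unknown)
        changed = int(np.count_nonzero(new_alpha != alpha))
        alpha = new_alpha
        logger.debug("graph-cut iteration %d: %d labels changed", it + 1, changed)
        if changed == 0:
            break

    full = np.zeros(trimap.shape, dtype=bool)
    full[y0:y1, x0:x1] = alpha
    return full
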