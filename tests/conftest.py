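import numpy as np
import pytest

from posturekit import MannequinSpec, generate
from posturekit.keypoints import Keypoint2D, PoseKeypoints


@pytest.fixture(scope="session")
def clean_sagittal():
    """Noise-free, jitter-free sagittal fixture at 40 deg flexion."""
    spec = MannequinSpec(view="sagittal", trunk_angle_deg=40.0,
                         keypoint_jitter_sigma=0.0, noise_sigma=0.0, seed=3)
    image, mask, truth = generate(spec)
    return image, mask, truth


@pytest.fixture(scope="session")
def clean_frontal():
    """Noise-free, jitter-free frontal fixture at 15 deg lean."""
    spec = MannequinSpec(view="frontal", trunk_angle_deg=15.0,
                         keypoint_jitter_sigma=0.0, noise_sigma=0.0, seed=3)
    image, mask, truth = generate(spec)
    return image, mask, truth


def make_keypoints(points, view="frontal", width=1000, height=1000):
    """Hand-written PoseKeypoints from a name -> (x, y) mapping."""
    return PoseKeypoints(
        {name: Keypoint2D(float(x), float(y), 0.9) for name, (x, y) in points.items()},
        view=view, image_width=width, image_height=height,
    )


def random_blob_mask(rng, size=64):
    """Random connected blob mask: union of a few discs, largest component."""
    from scipy import ndimage

    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    n_discs = rng.integers(2, 6)
    cx0, cy0 = rng.uniform(size * 0.3, size * 0.7, size=2)
    cx, cy = cx0, cy0
    for _ in range(n_discs):
        r = rng.uniform(size * 0.08, size * 0.25)
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        cx = np.clip(cx + rng.uniform(-r, r), 2, size - 3)
        cy = np.clip(cy + rng.uniform(-r, r), 2, size - 3)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask
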