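"""Typed errors raised across the measurement pipeline.

Each stage fails loudly rather than imputing data: a silently guessed
keypoint or landmark would corrupt a clinical angle.
"""


class PostureError(Exception):
    """Base class for all posturekit errors."""


class FormatError(PostureError):
    """Malformed input file (pose JSON, landmark JSON, manifest)."""


class EmptyDetectionError(PostureError):
    """A pose file contains no detected people."""


class MissingKeypointError(PostureError):
    """An operation requires a keypoint that is absent (confidence 0)."""

    def __init__(self, names):
        if isinstance(names, str):
            names = [names]
        self.names = list(names)
        super().__init__(f"required keypoint(s) missing: {', '.join(self.names)}")


class GeometryError(PostureError):
    """Degenerate geometry: zero-length segment, parallel lines, ..."""


class SegmentationError(PostureError):
    """Graph-cut segmentation failed or its preconditions are violated."""


class LandmarkError(PostureError):
    """A silhouette-based landmark search failed (seed outside mask,
    march exits the image, no posterior boundary pixel)."""
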