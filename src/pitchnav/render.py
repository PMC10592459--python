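"""Synthetic frame renderer: validation fixture for the detector.

Renders an elongated two-part animal — a trunk ellipse plus a brighter
head disc, both centered on the body axis — at a known pose over a given
background, with optional Gaussian pixel noise.  Because both parts are
symmetric about the axis, the blob's principal axis coincides exactly with
the posed pitch direction, giving the detector a pixel-accurate ground
truth.

Pose coordinates follow the package convention: ``x`` is the column,
``z`` increases upward (row ``H - 1 - z``), pitch in degrees nose-up
positive, ``heading`` +1 for rightward and -1 for leftward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Pose", "make_background", "render_frame", "render_with_truth"]


@dataclass
class Pose:
    x: float
    z: float
    pitch: float  # deg, nose-up positive
    heading: int = 1  # +1 right, -1 left
    length: float = 40.0  # px

    def direction(self) -> np.ndarray:
        th = np.radians(self.pitch)
        return np.array([np.cos(th) * self.heading, np.sin(th)])


TRUNK_AMPLITUDE = 120.0
HEAD_AMPLITUDE = 200.0
# geometry as fractions of total length
TRUNK_SEMI_MAJOR = 0.30
TRUNK_SEMI_MINOR = 0.10
HEAD_OFFSET = 0.30
HEAD_RADIUS = 0.11


def make_background(
    shape: tuple[int, int] = (220, 220),
    level: float = 30.0,
    gradient: float = 10.0,
) -> np.ndarray:
    """Flat background with a mild vertical gradient (no noise)."""
    H, W = shape
    rows = np.linspace(0.0, 1.0, H)[:, None]
    return level + gradient * rows * np.ones((1, W))


def _smooth_mask(d: np.ndarray) -> np.ndarray:
    """~1 px antialiased edge from a signed 'inside' distance d (px)."""
    return np.clip(d + 0.5, 0.0, 1.0)


def _paint(pose: Pose, shape: tuple[int, int]) -> np.ndarray:
    """Noise-free additive intensity raster of the animal."""
    H, W = shape
    L = pose.length
    d = pose.direction()
    trunk_c = np.array([pose.x, pose.z])
    head_c = trunk_c + HEAD_OFFSET * L * d

    extent = L  # generous bounding box half-size
    c_lo = max(int(pose.x - extent), 0)
    c_hi = min(int(pose.x + extent) + 1, W)
    r_lo = max(int((H - 1 - pose.z) - extent), 0)
    r_hi = min(int((H - 1 - pose.z) + extent) + 1, H)
    cols = np.arange(c_lo, c_hi)
    rows = np.arange(r_lo, r_hi)
    X, R = np.meshgrid(cols.astype(float), rows.astype(float))
    Z = (H - 1.0) - R

    # trunk ellipse in axis-aligned coordinates
    u = (X - trunk_c[0]) * d[0] + (Z - trunk_c[1]) * d[1]
    v = -(X - trunk_c[0]) * d[1] + (Z - trunk_c[1]) * d[0]
    a, b = TRUNK_SEMI_MAJOR * L, TRUNK_SEMI_MINOR * L
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    trunk = _smooth_mask((1.0 - rho) * b) * TRUNK_AMPLITUDE

    rr = np.hypot(X - head_c[0], Z - head_c[1])
    head = _smooth_mask(HEAD_RADIUS * L - rr) * HEAD_AMPLITUDE

    patch = np.maximum(trunk, head)
    out = np.zeros(shape)
    out[r_lo:r_hi, c_lo:c_hi] = patch
    return out


def render_frame(
    pose: Pose,
    background: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame: animal painted over the background plus noise.

    Raises if the pose (including the body extent) leaves the frame.
    """
    H, W = background.shape
    margin = pose.length * 0.55
    if not (margin <= pose.x <= W - 1 - margin and margin <= pose.z <= H - 1 - margin):
        raise ValueError(f"pose ({pose.x:.1f}, {pose.z:.1f}) out of frame bounds")
    frame = background + _paint(pose, background.shape)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        frame = frame + rng.normal(0.0, noise_sd, frame.shape)
    return frame


def render_with_truth(
    pose: Pose,
    background: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Render a frame and return the noise-free ground truth.

    Truth fields: posed ``pitch``, head-disc center ``head``, trunk center
    ``trunk``, the intensity-weighted centroid ``centroid`` of the
    noise-free blob, and the blob ``mask`` (noise-free pixels above zero).
    """
    frame = render_frame(pose, background, noise_sd, rng)
    paint = _paint(pose, background.shape)
    rows, cols = np.nonzero(paint > 0)
    w = paint[rows, cols]
    H = background.shape[0]
    xz = np.column_stack([cols.astype(float), (H - 1.0) - rows])
    centroid = (xz * w[:, None]).sum(axis=0) / w.sum()
    d = pose.direction()
    truth = {
        "pitch": pose.pitch,
        "trunk": (pose.x, pose.z),
        "head": tuple(np.array([pose.x, pose.z]) + HEAD_OFFSET * pose.length * d),
        "centroid": tuple(centroid),
        "mask": paint > 0,
    }
    return frame, truth
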