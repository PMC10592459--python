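"""Single-animal detection and orientation on grayscale frames.

Re-implementation of the real-time acquisition algorithm: (1) background
subtraction, (2) noise thresholding, (3) rejection of frames with zero or
more than one animal in view, (4) size/intensity criteria splitting the
blob into two parts (body and head), (5) extraction of location and body
orientation relative to the horizon.

Conventions: frames are ``(H, W)`` grayscale arrays indexed ``[row, col]``
with row 0 at the top; all *outputs* are in physical coordinates
``x = col`` and ``z = (H - 1) - row`` so that z increases upward and pitch
is nose-up positive.  Pitch is reported in ``(-90, 90]`` degrees and is
invariant to the animal's left/right heading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectorThresholds",
    "DetectionResult",
    "subtract_background",
    "estimate_background",
    "split_parts",
    "orientation_from_parts",
    "detect_animal",
]

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class DetectorThresholds:
    """Background model and blob acceptance criteria.

    ``area_min``/``area_max`` bound the pixel count of an acceptable
    animal blob; ``intensity_ratio`` is the minimum brighter/dimmer mean
    intensity ratio for the intensity criterion to resolve head vs. body,
    and ``size_ratio`` the analogous area ratio for the fallback size
    criterion (the head part is smaller).
    """

    background: np.ndarray
    noise_threshold: float = 12.0
    area_min: int = 60
    area_max: int = 20000
    intensity_ratio: float = 1.15
    size_ratio: float = 1.3

    def __post_init__(self) -> None:
        if self.area_min >= self.area_max:
            raise ValueError("area_min must be below area_max")


@dataclass
class DetectionResult:
    accepted: bool
    body: tuple[float, float] | None = None  # (x, z), z up
    head: tuple[float, float] | None = None
    pitch: float | None = None  # deg, nose-up positive
    animal_length: float | None = None  # px, moment-based major-axis length
    rejection_reason: str | None = None  # no_animal | multiple_animals |
    #                                      size_out_of_bounds | parts_unresolved


def estimate_background(frames: np.ndarray) -> np.ndarray:
    """Per-pixel temporal median over a sample of frames.

    The median is robust to the transiently present animal as long as it
    occupies any given pixel in fewer than half the sampled frames.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected a (n_frames, H, W) stack")
    return np.median(frames, axis=0)


def subtract_background(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Nonnegative absolute-difference raster."""
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {background.shape}")
    return np.abs(frame - background)


def _weighted_axis(xz: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted centroid, principal-axis unit vector, eigenvalues."""
    wsum = w.sum()
    centroid = (xz * w[:, None]).sum(axis=0) / wsum
    d = xz - centroid
    cov = (d * w[:, None]).T @ d / wsum
    evals, evecs = np.linalg.eigh(cov)
    return centroid, evecs[:, -1], evals


def split_parts(
    xz: np.ndarray,
    intensities: np.ndarray,
    intensity_ratio: float = 1.15,
    size_ratio: float = 1.3,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Split one blob into (body, head) index arrays, or ``None``.

    A two-class intensity-weighted split of the pixel projections onto the
    blob's principal axis proposes the two parts; the brighter part is the
    head if the mean-intensity contrast passes ``intensity_ratio``,
    otherwise the smaller part is the head if the area contrast passes
    ``size_ratio``.  If neither criterion separates the parts (e.g. a
    uniform circular blob) the split is unresolved and ``None`` is
    returned.
    """
    xz = np.asarray(xz, float)
    w = np.asarray(intensities, float)
    if len(xz) < 4:
        return None
    centroid, axis, _ = _weighted_axis(xz, w)
    proj = (xz - centroid) @ axis
    # weighted 2-means in 1-D
    c1, c2 = np.percentile(proj, [25, 75])
    if c1 == c2:
        return None
    for _ in range(25):
        to2 = np.abs(proj - c2) < np.abs(proj - c1)
        if to2.all() or (~to2).all():
            return None
        n1 = (w[~to2] * proj[~to2]).sum() / w[~to2].sum()
        n2 = (w[to2] * proj[to2]).sum() / w[to2].sum()
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    part1 = np.flatnonzero(~to2)
    part2 = np.flatnonzero(to2)
    m1, m2 = w[part1].mean(), w[part2].mean()
    bright, dim = (part2, part1) if m2 > m1 else (part1, part2)
    if max(m1, m2) / max(min(m1, m2), 1e-12) >= intensity_ratio:
        head, body = bright, dim
    elif max(len(part1), len(part2)) / min(len(part1), len(part2)) >= size_ratio:
        head, body = (
            (part1, part2) if len(part1) < len(part2) else (part2, part1)
        )
    else:
        return None
    return body, head


def orientation_from_parts(
    body: tuple[float, float], head: tuple[float, float]
) -> float:
    """Pitch (deg) of the head-minus-body vector relative to horizontal.

    Nose-up positive and independent of left/right heading: a fish at +20
    degrees pitches +20 whether it faces left or right.
    """
    dx = head[0] - body[0]
    dz = head[1] - body[1]
    if dx == 0 and dz == 0:
        raise ValueError("coincident body and head centroids")
    return float(np.degrees(np.arctan2(dz, abs(dx))))


def detect_animal(frame: np.ndarray, thresholds: DetectorThresholds) -> DetectionResult:
    """Run the full detection chain on one frame.

    Exactly one connected component within the area bounds is required;
    anything else is a rejection (a result, not an error).  Orientation
    comes from the blob's intensity-weighted principal axis, with the
    head/body part centroids disambiguating the nose direction.
    """
    diff = subtract_background(frame, thresholds.background)
    mask = diff > thresholds.noise_threshold
    labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONN)
    if n_comp == 0:
        return DetectionResult(False, rejection_reason="no_animal")
    areas = np.bincount(labels.ravel())[1:]
    in_bounds = np.flatnonzero(
        (areas >= thresholds.area_min) & (areas <= thresholds.area_max)
    ) + 1
    if len(in_bounds) == 0:
        # components exist but none has a plausible animal size; tiny
        # specks are noise (no animal), anything else is a size failure
        reason = (
            "no_animal" if areas.max() < thresholds.area_min else "size_out_of_bounds"
        )
        return DetectionResult(False, rejection_reason=reason)
    if len(in_bounds) > 1:
        return DetectionResult(False, rejection_reason="multiple_animals")

    rows, cols = np.nonzero(labels == in_bounds[0])
    H = frame.shape[0]
    xz = np.column_stack([cols.astype(float), (H - 1.0) - rows])
    w = diff[rows, cols]
    parts = split_parts(xz, w, thresholds.intensity_ratio, thresholds.size_ratio)
    if parts is None:
        return DetectionResult(False, rejection_reason="parts_unresolved")
    body_idx, head_idx = parts

    def _centroid(idx: np.ndarray) -> np.ndarray:
        return (xz[idx] * w[idx, None]).sum(axis=0) / w[idx].sum()

    body_c = _centroid(body_idx)
    head_c = _centroid(head_idx)
    _, axis, evals = _weighted_axis(xz, w)
    direction = axis * np.sign(axis @ (head_c - body_c))
    pitch = float(np.degrees(np.arctan2(direction[1], abs(direction[0]))))
    # major-axis length of an equivalent uniform ellipse: 4*sqrt(lambda_max)
    length = float(4.0 * np.sqrt(evals[-1]))
    return DetectionResult(
        accepted=True,
        body=(float(body_c[0]), float(body_c[1])),
        head=(float(head_c[0]), float(head_c[1])),
        pitch=pitch,
        animal_length=length,
        rejection_reason=None,
    )
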