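"""Per-bout kinematic features.

From each peak-aligned bout window this stage derives the quantities the
four balance/navigation models consume:

* trajectory — tangential angle of the instantaneous displacement at peak
  speed (climbing positive, invariant to left/right heading);
* attack angle — trajectory minus pitch at peak speed, the fin-generated
  lift component of a climb;
* steering rotation — pitch change from the initial posture (-250 ms) to
  peak speed, split at the time of maximal angular velocity into the body
  rotation (before) and the residual rotation (after);
* righting rotation — corrective pitch change from peak speed to +100 ms.

Angular velocity is computed from pitch smoothed with a centered 11-frame
moving average (the window shrinks symmetrically at the edges); bouts that
begin with nose-down rotation have their angular-velocity sign flipped so
that every bout starts with positive angular velocity, and the time of peak
angular velocity is the argmax of the per-timepoint median of the adjusted
series over the pre-peak steering phase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .segment import BoutCollection

__all__ = [
    "smooth_centered",
    "angular_velocity",
    "peak_angvel_time",
    "bout_trajectory",
    "compute_features",
]

FEATURE_COLUMNS = [
    "epoch_id",
    "repeat_id",
    "t_peak",
    "peak_speed",
    "pitch_initial",
    "pitch_peak",
    "pitch_post",
    "trajectory",
    "traj_deviation",
    "attack_angle",
    "steering_rotation",
    "body_rotation",
    "residual_rotation",
    "righting_rotation",
    "t_maxangvel_ms",
]


def smooth_centered(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis.

    Near the edges the window shrinks symmetrically (half-width
    ``min(window//2, i, n-1-i)``) so no data is fabricated beyond the
    series; a linear series is left exactly unchanged.
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    n = arr.shape[-1]
    half = window // 2
    cs = np.concatenate([np.zeros(arr.shape[:-1] + (1,)), np.cumsum(arr, axis=-1)], axis=-1)
    out = np.empty_like(arr)
    idx = np.arange(n)
    halves = np.minimum(np.minimum(idx, n - 1 - idx), half)
    for h in np.unique(halves):
        cols = idx[halves == h]
        out[..., cols] = (cs[..., cols + h + 1] - cs[..., cols - h]) / (2 * h + 1)
    return out.reshape(np.shape(values))


def angular_velocity(
    bouts: BoutCollection, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed angular velocity and its sign-adjusted version.

    Returns ``(angvel, adjusted, flipped)`` where ``angvel`` is the first
    difference of the smoothed pitch divided by dt (``(n_bouts, window)``,
    first column back-filled), ``adjusted`` is ``angvel`` with the sign
    flipped for bouts whose initial rotation (mean angular velocity over
    [-250, -100] ms) is nose-down, and ``flipped`` is that boolean mask.
    """
    fr = bouts.frame_rate
    dt = 1.0 / fr
    smoothed = smooth_centered(bouts.pitch, config.smooth_window_frames)
    av = np.empty_like(smoothed)
    av[:, 1:] = np.diff(smoothed, axis=1) / dt
    av[:, 0] = av[:, 1]
    lo = bouts.i_peak - config.frames(config.reserved_pre_ms, fr)
    hi = bouts.i_peak - config.frames(config.ibi_buffer_ms, fr)
    initial = av[:, lo : hi + 1].mean(axis=1)
    flipped = initial < 0
    adjusted = np.where(flipped[:, None], -av, av)
    return av, adjusted, flipped


def peak_angvel_time(
    bouts: BoutCollection, config: AnalysisConfig, adjusted: np.ndarray | None = None
) -> float:
    """Time of peak angular velocity (ms relative to peak speed).

    The per-timepoint median of the adjusted angular velocity is taken
    across all bouts (normally the bouts of one experimental repeat) and
    its argmax located within the pre-peak steering phase
    [-reserved_pre_ms, 0].  Callers average the per-repeat values.
    """
    if len(bouts) == 0:
        raise ValueError("no bouts")
    if adjusted is None:
        _, adjusted, _ = angular_velocity(bouts, config)
    fr = bouts.frame_rate
    lo = bouts.i_peak - config.frames(config.reserved_pre_ms, fr)
    med = np.median(adjusted[:, lo : bouts.i_peak + 1], axis=0)
    # the first difference over (i-1, i) estimates the derivative at the
    # interval midpoint: assign it there to avoid a half-frame bias
    return float((lo + int(np.argmax(med)) - 0.5 - bouts.i_peak) * 1000.0 / fr)


def bout_trajectory(bouts: BoutCollection) -> np.ndarray:
    """Tangential angle of the instantaneous displacement at peak speed (deg).

    Uses the central displacement spanning peak +/- 1 frame.  The forward
    direction is the sign of the net x displacement over the whole bout, so
    a fish climbing at 45 degrees reports +45 whether it swims leftward or
    rightward.
    """
    p = bouts.i_peak
    dx = bouts.x[:, p + 1] - bouts.x[:, p - 1]
    dz = bouts.z[:, p + 1] - bouts.z[:, p - 1]
    net = bouts.x[:, -1] - bouts.x[:, 0]
    sign = np.sign(net)
    sign = np.where(sign == 0, np.sign(dx), sign)
    if np.any((dx == 0) & (dz == 0)):
        raise ValueError("zero displacement at peak speed")
    # sign may still be 0 for a purely vertical bout; atan2(dz, 0) is fine
    return np.degrees(np.arctan2(dz, sign * dx))


def compute_features(
    bouts: BoutCollection,
    t_maxangvel_ms: float,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Full per-bout feature table.

    ``t_maxangvel_ms`` is the (negative) time of maximal angular velocity
    used to split the steering rotation into body and residual components;
    it normally comes from :func:`peak_angvel_time` on the same repeat.
    The decomposition ``steering = body + residual`` holds exactly by
    construction.
    """
    fr = bouts.frame_rate
    if not -config.reserved_pre_ms <= t_maxangvel_ms <= 0:
        raise ValueError(
            f"t_maxangvel_ms must lie in [-{config.reserved_pre_ms:g}, 0] ms"
        )
    p = bouts.i_peak
    i_init = p - config.frames(config.reserved_pre_ms, fr)
    i_post = p + config.frames(config.righting_window_ms, fr)
    i_mav = p + config.frames(t_maxangvel_ms, fr)  # negative offset

    pitch_initial = bouts.pitch[:, i_init]
    pitch_peak = bouts.pitch[:, p]
    pitch_post = bouts.pitch[:, i_post]
    pitch_mav = bouts.pitch[:, i_mav]
    trajectory = bout_trajectory(bouts)

    df = pd.DataFrame(
        {
            "epoch_id": bouts.epoch_id,
            "repeat_id": bouts.repeat_id,
            "t_peak": bouts.t_peak,
            "peak_speed": bouts.peak_speed,
            "pitch_initial": pitch_initial,
            "pitch_peak": pitch_peak,
            "pitch_post": pitch_post,
            "trajectory": trajectory,
            "traj_deviation": trajectory - pitch_initial,
            "attack_angle": trajectory - pitch_peak,
            "steering_rotation": pitch_peak - pitch_initial,
            "body_rotation": pitch_mav - pitch_initial,
            "residual_rotation": pitch_peak - pitch_mav,
            "righting_rotation": pitch_post - pitch_peak,
            "t_maxangvel_ms": np.full(len(bouts), t_maxangvel_ms),
        }
    )
    return df[FEATURE_COLUMNS]
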