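"""Segmentation of raw traces into epochs, swim bouts and inter-bout intervals.

Larval zebrafish swim in discrete episodes of translation ("swim bouts").
A bout is the maximal interval in which the instantaneous speed exceeds
5 mm/s; each bout is represented by a peak-speed-aligned window running
from 500 ms before to 300 ms after the time of peak speed (83 + 1 + 50
frames at 166 Hz).  The sub-threshold interval between two consecutive
bouts, shortened by a 100 ms buffer at each end to absorb detection error,
is the inter-bout interval (IBI); its reciprocal is the bout frequency used
by the movement-timing model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import RunMetadata

__all__ = [
    "Epoch",
    "Bout",
    "BoutCollection",
    "compute_speed",
    "epochs_from_trace",
    "qc_epochs",
    "supra_threshold_runs",
    "extract_bouts",
    "extract_ibis",
]


@dataclass
class Epoch:
    """One contiguous interval of valid single-animal detection."""

    epoch_id: int
    t: np.ndarray  # s, from the trace time stamps
    x: np.ndarray  # mm
    z: np.ndarray  # mm, up positive
    pitch: np.ndarray  # deg, nose-up positive
    frame_rate: float
    speed: np.ndarray = field(default=None)  # mm/s, filled on construction

    def __post_init__(self) -> None:
        if self.speed is None and len(self.t) >= 2:
            self.speed = compute_speed(self.x, self.z, 1.0 / self.frame_rate)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


def compute_speed(x: np.ndarray, z: np.ndarray, dt: float) -> np.ndarray:
    """Instantaneous speed from (x, z) positions in mm.

    ``speed[i]`` is the Euclidean displacement between frames ``i-1`` and
    ``i`` divided by ``dt``; ``speed[0]`` is back-filled from ``speed[1]``
    so the series has one value per frame.
    """
    if len(x) < 2:
        raise ValueError("speed requires at least two frames")
    disp = np.hypot(np.diff(x), np.diff(z))
    speed = np.empty(len(x))
    speed[1:] = disp / dt
    speed[0] = speed[1]
    return speed


def epochs_from_trace(trace: pd.DataFrame, meta: RunMetadata) -> list[Epoch]:
    """Split a raw trace into :class:`Epoch` objects in mm units.

    Single-frame epochs are dropped (no speed is definable; they could
    never pass QC).
    """
    epochs = []
    for eid, grp in trace.groupby("epoch_id", sort=True):
        if len(grp) < 2:
            continue
        epochs.append(
            Epoch(
                epoch_id=int(eid),
                t=grp["time_stamp"].to_numpy(float),
                x=grp["body_x"].to_numpy(float) * meta.mm_per_pixel,
                z=grp["body_z"].to_numpy(float) * meta.mm_per_pixel,
                pitch=grp["pitch"].to_numpy(float),
                frame_rate=meta.frame_rate,
            )
        )
    return epochs


def qc_epochs(
    epochs: list[Epoch], config: AnalysisConfig
) -> tuple[list[Epoch], dict[str, int]]:
    """Keep epochs longer than 2.5 s whose maximum speed exceeds 5 mm/s.

    Optional plausibility filters (frame-to-frame displacement, pitch jump)
    are applied only when configured.  Returns the retained epochs and a
    per-reason rejection count.
    """
    retained: list[Epoch] = []
    counts = {"too_short": 0, "too_slow": 0, "displacement": 0, "pitch_jump": 0}
    dt_ms = 1000.0
    for ep in epochs:
        if ep.duration <= config.epoch_min_duration_s:
            counts["too_short"] += 1
            continue
        if np.max(ep.speed) <= config.speed_threshold_mm_s:
            counts["too_slow"] += 1
            continue
        if config.max_displacement_mm is not None:
            if np.max(np.hypot(np.diff(ep.x), np.diff(ep.z))) > config.max_displacement_mm:
                counts["displacement"] += 1
                continue
        if config.max_pitch_jump_deg is not None:
            if np.max(np.abs(np.diff(ep.pitch))) > config.max_pitch_jump_deg:
                counts["pitch_jump"] += 1
                continue
        retained.append(ep)
    return retained, counts


def supra_threshold_runs(speed: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of frames with ``speed > threshold``.

    Returns ``(start, end)`` index pairs with both ends inclusive.
    """
    above = np.asarray(speed) > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    return list(zip(starts, ends))


@dataclass
class Bout:
    """One peak-speed-aligned swim bout window."""

    epoch_id: int
    repeat_id: int
    peak_index: int  # frame index of the peak within the epoch
    run: tuple[int, int]  # supra-threshold run bounds within the epoch
    t_peak: float  # epoch time of the peak (s)
    speed: np.ndarray
    pitch: np.ndarray
    x: np.ndarray
    z: np.ndarray
    i_peak: int  # index of the peak within the window arrays
    frame_rate: float

    @property
    def peak_speed(self) -> float:
        return float(self.speed[self.i_peak])


def extract_bouts(
    epoch: Epoch, config: AnalysisConfig, repeat_id: int = 0
) -> list[Bout]:
    """Extract aligned bouts from a QC-passed epoch.

    Each maximal supra-threshold run yields one candidate bout at the run's
    speed argmax (earliest frame on ties).  Candidates whose full
    [-pre_peak, +post_peak] window does not fit inside the epoch are
    dropped.  Overlapping windows from distinct runs are all kept.
    """
    fr = epoch.frame_rate
    pre = config.pre_frames(fr)
    post = config.post_frames(fr)
    bouts: list[Bout] = []
    for start, end in supra_threshold_runs(epoch.speed, config.speed_threshold_mm_s):
        seg = epoch.speed[start : end + 1]
        peak = start + int(np.argmax(seg))
        lo, hi = peak - pre, peak + post
        if lo < 0 or hi >= epoch.n_frames:
            continue
        sl = slice(lo, hi + 1)
        bouts.append(
            Bout(
                epoch_id=epoch.epoch_id,
                repeat_id=repeat_id,
                peak_index=peak,
                run=(start, end),
                t_peak=float(epoch.t[peak]),
                speed=epoch.speed[sl].copy(),
                pitch=epoch.pitch[sl].copy(),
                x=epoch.x[sl].copy(),
                z=epoch.z[sl].copy(),
                i_peak=pre,
                frame_rate=fr,
            )
        )
    return bouts


def extract_ibis(
    epoch: Epoch, bouts: list[Bout], config: AnalysisConfig
) -> pd.DataFrame:
    """Inter-bout intervals between consecutive bouts of one epoch.

    The raw gap is the time between the last supra-threshold frame of one
    bout's run and the first supra-threshold frame of the next; the IBI
    duration is that gap minus a buffer at each end.  Intervals with a
    non-positive corrected duration, and bout pairs separated by an
    additional (window-clipped, hence unreported) supra-threshold run, are
    discarded.  Mean pitch is computed over the buffered (shortened)
    interval.
    """
    cols = [
        "epoch_id",
        "duration",
        "bout_frequency",
        "ibi_pitch",
        "pre_bout_peak_index",
        "post_bout_peak_index",
    ]
    if len(bouts) < 2:
        return pd.DataFrame(columns=cols)
    buffer_s = config.ibi_buffer_ms / 1000.0
    all_runs = supra_threshold_runs(epoch.speed, config.speed_threshold_mm_s)
    rows = []
    ordered = sorted(bouts, key=lambda b: b.peak_index)
    for a, b in zip(ordered[:-1], ordered[1:]):
        gap_lo, gap_hi = a.run[1], b.run[0]
        # another run between the two bouts means the gap is not fully
        # sub-threshold: no valid IBI
        if any(gap_lo < s and e < gap_hi for s, e in all_runs):
            continue
        gap = float(epoch.t[gap_hi] - epoch.t[gap_lo])
        duration = gap - 2.0 * buffer_s
        if duration <= 0:
            continue
        t0, t1 = epoch.t[gap_lo] + buffer_s, epoch.t[gap_hi] - buffer_s
        inside = (epoch.t >= t0) & (epoch.t <= t1)
        ibi_pitch = float(np.mean(epoch.pitch[inside])) if inside.any() else np.nan
        rows.append(
            {
                "epoch_id": epoch.epoch_id,
                "duration": duration,
                "bout_frequency": 1.0 / duration,
                "ibi_pitch": ibi_pitch,
                "pre_bout_peak_index": a.peak_index,
                "post_bout_peak_index": b.peak_index,
            }
        )
    return pd.DataFrame(rows, columns=cols)


class BoutCollection:
    """Stack of aligned bouts as 2-D arrays, one row per bout.

    This is the container the kinematics stage operates on: ``speed``,
    ``pitch``, ``x`` and ``z`` are ``(n_bouts, window)`` arrays with the
    peak-speed frame at column ``i_peak``.
    """

    def __init__(self, bouts: list[Bout]):
        if not bouts:
            raise ValueError("empty bout list")
        window = {len(b.speed) for b in bouts}
        if len(window) != 1:
            raise ValueError("bouts have inconsistent window lengths")
        self._bouts = bouts
        self.speed = np.stack([b.speed for b in bouts])
        self.pitch = np.stack([b.pitch for b in bouts])
        self.x = np.stack([b.x for b in bouts])
        self.z = np.stack([b.z for b in bouts])
        self.i_peak = bouts[0].i_peak
        self.frame_rate = bouts[0].frame_rate
        self.epoch_id = np.array([b.epoch_id for b in bouts])
        self.repeat_id = np.array([b.repeat_id for b in bouts])
        self.t_peak = np.array([b.t_peak for b in bouts])

    def __len__(self) -> int:
        return len(self._bouts)

    def __getitem__(self, i: int) -> Bout:
        return self._bouts[i]

    @property
    def window(self) -> int:
        return self.speed.shape[1]

    @property
    def peak_speed(self) -> np.ndarray:
        return self.speed[:, self.i_peak]

    def time_ms(self) -> np.ndarray:
        """Time of each window column in ms relative to peak speed."""
        idx = np.arange(self.window) - self.i_peak
        return idx * 1000.0 / self.frame_rate
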