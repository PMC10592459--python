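"""Global analysis configuration.

Every numeric threshold used by the segmentation, kinematics, model-fitting
and resolution stages lives here, so a whole analysis is reproducible from
one YAML file.  Defaults are the values used throughout the zebrafish
balance/navigation analyses: a 5 mm/s instantaneous-speed threshold defines
swim bouts, bouts are windowed from 500 ms before to 300 ms after peak
speed, inter-bout intervals lose a 100 ms buffer at each end, and so on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    """Numeric parameters for the full analysis pipeline.

    Parameters
    ----------
    speed_threshold_mm_s
        Instantaneous speed above which a fish is considered to be in a
        swim bout (mm/s).
    finbody_speed_floor_mm_s
        Minimum peak speed for a bout to enter the fin-body (attack angle
        vs. body rotation) fit (mm/s).
    epoch_min_duration_s
        Epochs shorter than this are discarded during QC (s).
    pre_peak_ms, post_peak_ms
        Extent of the peak-aligned bout window (ms before / after the time
        of peak speed).  500 + 300 ms -> 134 frames at 166 Hz.
    reserved_pre_ms, reserved_post_ms
        Margins of the window reserved for future analysis; "initial" pitch
        is read at ``-reserved_pre_ms``.
    ibi_buffer_ms
        Buffer deducted from each end of a sub-threshold interval when
        computing inter-bout interval duration (ms).
    righting_window_ms
        Righting rotation is the pitch change from peak speed to this many
        ms after peak.
    smooth_window_frames
        Centered moving-average window (frames) applied to pitch before
        differentiating into angular velocity.
    ibi_pitch_bin_deg, rotation_bin_deg_scatter, rotation_bin_deg_fit
        Bin widths (deg) used for display-only binned averages.
    ci_level
        Confidence level for CI-width resampling.
    resample_repeats
        Outer resampling repeats per sample size (CI widths and effect-size
        surfaces).
    effectsize_draws
        Bootstrap draws per dataset inside one Cohen's d computation.
    fixed_tmaxangvel_ms
        Fixed time of maximal angular velocity (ms, relative to peak speed)
        used for fin-body features inside the effect-size simulation.
    variance_convention
        ``"as_printed"`` or ``"delta_method"``; see
        :func:`pitchnav.models.finbody_variance`.
    righting_initial
        Which posture the righting regression uses as "initial":
        ``"pre_bout_pitch"`` (pitch at -250 ms, default) or
        ``"ibi_pitch"``.
    max_displacement_mm, max_pitch_jump_deg, max_length_cv
        Optional epoch QC filters; ``None`` disables each (all disabled by
        default).
    """

    speed_threshold_mm_s: float = 5.0
    finbody_speed_floor_mm_s: float = 7.0
    epoch_min_duration_s: float = 2.5
    pre_peak_ms: float = 500.0
    post_peak_ms: float = 300.0
    reserved_pre_ms: float = 250.0
    reserved_post_ms: float = 200.0
    ibi_buffer_ms: float = 100.0
    righting_window_ms: float = 100.0
    smooth_window_frames: int = 11
    ibi_pitch_bin_deg: float = 3.0
    rotation_bin_deg_scatter: float = 0.5
    rotation_bin_deg_fit: float = 0.8
    ci_level: float = 0.95
    resample_repeats: int = 20
    effectsize_draws: int = 200
    fixed_tmaxangvel_ms: float = 40.0
    rng_seed: int = 0
    variance_convention: str = "as_printed"
    righting_initial: str = "pre_bout_pitch"
    max_displacement_mm: float | None = None
    max_pitch_jump_deg: float | None = None
    max_length_cv: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "pre_peak_ms",
            "post_peak_ms",
            "reserved_pre_ms",
            "reserved_post_ms",
            "ibi_buffer_ms",
            "righting_window_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smooth_window_frames < 1:
            raise ValueError("smooth_window_frames must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.variance_convention not in ("as_printed", "delta_method"):
            raise ValueError("variance_convention must be 'as_printed' or 'delta_method'")
        if self.righting_initial not in ("pre_bout_pitch", "ibi_pitch"):
            raise ValueError("righting_initial must be 'pre_bout_pitch' or 'ibi_pitch'")

    # frame-index helpers -------------------------------------------------

    def frames(self, ms: float, frame_rate: float) -> int:
        """Convert a duration in ms to a frame count, ``round(ms*fr/1000)``."""
        return int(round(ms * frame_rate / 1000.0))

    def pre_frames(self, frame_rate: float) -> int:
        return self.frames(self.pre_peak_ms, frame_rate)

    def post_frames(self, frame_rate: float) -> int:
        return self.frames(self.post_peak_ms, frame_rate)

    def window_frames(self, frame_rate: float) -> int:
        """Total bout window length in frames (pre + peak + post)."""
        return self.pre_frames(frame_rate) + 1 + self.post_frames(frame_rate)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML file (missing keys keep defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
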